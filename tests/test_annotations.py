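import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hierseg import (
    AnnotationError,
    FlatSegmentation,
    Hierarchy,
    Segment,
    align_pair,
    read_annotation,
    sample_labels,
    write_annotation,
)
from hierseg.synthetic import SyntheticSpec, random_hierarchy


class TestParsing:
    def test_single_line_lab(self, tmp_path):
        p = tmp_path / "one.lab"
        p.write_text("0.0 180.0 A\n")
        h = read_annotation(p)
        assert h.depth == 1
        assert h.duration == 180.0
        assert h.levels[0].segments[0] == Segment(0.0, 180.0, "A")

    def test_two_level_lab_pair(self, tmp_path):
        coarse = tmp_path / "coarse.lab"
        coarse.write_text("0.0 10.0 A\n10.0 25.0 B\n25.0 30.0 A\n")
        fine = tmp_path / "fine.lab"
        fine.write_text(
            "0.0 5.0 a\n5.0 10.0 b\n10.0 17.0 c\n17.0 25.0 c\n25.0 28.0 a\n28.0 30.0 b\n"
        )
        h = read_annotation([coarse, fine])
        assert h.depth == 2
        assert h.duration == 30.0
        assert len(h.levels[0]) == 3
        assert len(h.levels[1]) == 6
        assert all(abs(lvl.duration - 30.0) < 1e-9 for lvl in h.levels)

    def test_level_selection_drops_function(self, tmp_path):
        files = {}
        for name in ("coarse", "fine", "function"):
            p = tmp_path / f"{name}.txt"
            p.write_text("0.0\tA\n10.0\tB\n20.0\tEnd\n")
            files[name] = p
        h = read_annotation(files, format="salami_boundary", levels=["coarse", "fine"])
        assert h.depth == 2

    def test_salami_boundary_spans(self, tmp_path):
        p = tmp_path / "salami.txt"
        p.write_text("0.0\tA\n12.5\tB\n30.0\tEnd\n")
        h = read_annotation(p, format="salami_boundary")
        segs = h.levels[0].segments
        assert [s.label for s in segs] == ["A", "B"]
        assert segs[1].start == 12.5 and segs[1].end == 30.0

    def test_labels_case_sensitive_verbatim(self, tmp_path):
        p = tmp_path / "v.lab"
        p.write_text("0.0 1.0 A\n1.0 2.0 a\n2.0 3.0 A'\n")
        h = read_annotation(p)
        assert h.levels[0].label_set == {"A", "a", "A'"}

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.lab"
        p.write_text("0.0 1.0 A\nnot-a-time 2.0 B\n")
        with pytest.raises(AnnotationError, match=":2"):
            read_annotation(p)

    def test_large_gap_rejected(self, tmp_path):
        p = tmp_path / "gap.lab"
        p.write_text("0.0 1.0 A\n1.5 3.0 B\n")
        with pytest.raises(AnnotationError, match="gap"):
            read_annotation(p)

    def test_small_jitter_snapped_to_midpoint(self, tmp_path):
        p = tmp_path / "jitter.lab"
        p.write_text("0.0 1.004 A\n0.998 3.0 B\n")
        h = read_annotation(p)
        segs = h.levels[0].segments
        assert segs[0].end == segs[1].start == pytest.approx(1.001)

    def test_empty_level_rejected(self, tmp_path):
        p = tmp_path / "empty.lab"
        p.write_text("\n")
        with pytest.raises(AnnotationError, match="empty"):
            read_annotation(p)

    @pytest.mark.parametrize("fmt", ["interval_lab", "salami_boundary"])
    def test_write_read_round_trip(self, tmp_path, fmt):
        h = random_hierarchy(SyntheticSpec(duration=120.0, depth=2, seed=11))
        paths = [tmp_path / f"level{k}.lab" for k in range(h.depth)]
        write_annotation(h, paths, format=fmt)
        back = read_annotation(paths, format=fmt)
        assert back.depth == h.depth
        for lvl_a, lvl_b in zip(h.levels, back.levels):
            assert np.allclose(lvl_a.boundaries, lvl_b.boundaries, atol=1e-6)
            assert [s.label for s in lvl_a.segments] == [s.label for s in lvl_b.segments]


class TestValidation:
    def test_segment_requires_positive_span(self):
        with pytest.raises(AnnotationError):
            Segment(1.0, 1.0, "A")

    def test_segment_requires_label(self):
        with pytest.raises(AnnotationError):
            Segment(0.0, 1.0, "   ")

    def test_non_contiguous_segments_rejected(self):
        with pytest.raises(AnnotationError, match="contiguous"):
            FlatSegmentation((Segment(0.0, 1.0, "A"), Segment(2.0, 3.0, "B")))

    def test_levels_must_share_duration(self):
        a = FlatSegmentation((Segment(0.0, 10.0, "A"),))
        b = FlatSegmentation((Segment(0.0, 12.0, "a"),))
        with pytest.raises(AnnotationError, match="duration"):
            Hierarchy((a, b))


class TestSampling:
    def test_single_segment_at_10hz(self):
        h = Hierarchy((FlatSegmentation((Segment(0.0, 1.0, "A"),)),))
        g = sample_labels(h, 10.0)
        assert g.n_frames == 10
        assert np.all(g.labels[0] == g.labels[0][0])

    def test_half_open_convention(self):
        h = Hierarchy(
            (FlatSegmentation((Segment(0.0, 0.25, "A"), Segment(0.25, 0.6, "B"))),)
        )
        g = sample_labels(h, 10.0)
        # frames at t = 0.0 .. 0.5: boundary instant 0.25 is not hit, but
        # 0.3, 0.4, 0.5 fall in B; ceil(0.6 * 10) = 6 frames
        assert g.n_frames == 6
        assert list(g.labels[0]) == [0, 0, 0, 1, 1, 1]

    def test_boundary_instant_belongs_to_right_segment(self):
        h = Hierarchy(
            (FlatSegmentation((Segment(0.0, 0.5, "A"), Segment(0.5, 1.0, "B"))),)
        )
        g = sample_labels(h, 10.0)
        assert g.labels[0][5] != g.labels[0][4]

    def test_frame_count_contract(self, two_level_hierarchy):
        for rate in (4.0, 10.0, 7.3):
            g = sample_labels(two_level_hierarchy, rate)
            assert g.n_frames == math.ceil(two_level_hierarchy.duration * rate)
            assert g.labels.shape == (2, g.n_frames)

    def test_boundary_recovery_within_frame_period(self):
        h = random_hierarchy(SyntheticSpec(duration=90.0, depth=2, seed=5))
        rate = 10.0
        g = sample_labels(h, rate)
        for k, lvl in enumerate(h.levels):
            change = np.flatnonzero(np.diff(g.labels[k])) + 1
            # label changes are a subset of boundaries (adjacent repeats are
            # invisible); every recovered change-point must be near one
            for t in change / rate:
                assert np.min(np.abs(t - lvl.boundaries)) <= 1.0 / rate

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_recoding_invariance(self, seed):
        """Bijective relabeling leaves the grid's equality structure intact."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        labels = rng.integers(0, 4, size=n)
        names = np.array(["w", "x", "y", "z"])
        perm = rng.permutation(4)
        segs_a, segs_b = [], []
        for i, lab in enumerate(labels):
            segs_a.append(Segment(i * 1.0, (i + 1) * 1.0, names[lab]))
            segs_b.append(Segment(i * 1.0, (i + 1) * 1.0, names[perm[lab]]))
        ga = sample_labels(Hierarchy((FlatSegmentation(tuple(segs_a)),)), 2.0)
        gb = sample_labels(Hierarchy((FlatSegmentation(tuple(segs_b)),)), 2.0)
        eq_a = ga.labels[0][:, None] == ga.labels[0][None, :]
        eq_b = gb.labels[0][:, None] == gb.labels[0][None, :]
        assert np.array_equal(eq_a, eq_b)


class TestAlignment:
    def _h(self, duration, label="A"):
        return Hierarchy((FlatSegmentation((Segment(0.0, duration, label),)),))

    def test_equal_durations(self, two_level_hierarchy):
        g1, g2 = align_pair(two_level_hierarchy, two_level_hierarchy, 10.0)
        assert g1.n_frames == g2.n_frames == 360

    def test_small_mismatch_truncates_silently(self, caplog):
        with caplog.at_level(logging.WARNING, logger="hierseg.annotations"):
            g1, g2 = align_pair(self._h(180.0), self._h(180.4), 10.0, tolerance=1.0)
        assert g1.n_frames == g2.n_frames == 1800
        assert not caplog.records

    def test_large_mismatch_warns(self, caplog):
        with caplog.at_level(logging.WARNING, logger="hierseg.annotations"):
            g1, g2 = align_pair(self._h(180.0), self._h(200.0), 10.0, tolerance=1.0)
        assert g1.n_frames == g2.n_frames == 1800
        assert any("truncating" in r.message for r in caplog.records)

    def test_extreme_mismatch_fails(self):
        with pytest.raises(AnnotationError, match="factor"):
            align_pair(self._h(60.0), self._h(200.0), 10.0)
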