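import numpy as np
import pytest

from hierseg import (
    FeatureMatrix,
    FrameLabelGrid,
    annotation_distance,
    correlation_vector,
    delta_pipeline,
    meet_matrix,
    normalize_matrix,
    sample_labels,
    self_similarity,
    whitening_gram,
)
from hierseg.correlate import SelfSimilarityMatrix
from hierseg.features import FEATURE_KINDS
from hierseg.synthetic import SyntheticSpec, planted_features, random_hierarchy


def two_block_features(a, b, half: int = 4) -> FeatureMatrix:
    cols = np.concatenate(
        [np.tile(np.asarray(a, float)[:, None], (1, half)),
         np.tile(np.asarray(b, float)[:, None], (1, half))],
        axis=1,
    )
    return FeatureMatrix("chroma", cols, 4.0)


class TestSelfSimilarity:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        fm = FeatureMatrix("mfcc", rng.normal(size=(5, 12)), 4.0)
        g = self_similarity(fm).values
        assert np.allclose(np.diag(g), 1.0)
        assert np.allclose(g, g.T)
        assert np.all(g > 0) and np.all(g <= 1)

    def test_two_block_closed_form(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 2.0, 0.0])
        ssm = self_similarity(two_block_features(a, b))
        d2 = float(np.sum((a - b) ** 2))
        # each frame's squared distances: 3 zeros (within block, excluding
        # self) and 4 cross-block values of d2, plus the self 0: the median
        # over the 8 values per row is d2/2; sigma = mean of medians = d2/2
        sigma = d2 / 2
        assert ssm.bandwidth == pytest.approx(sigma)
        expected_cross = np.exp(-d2 / sigma)
        assert ssm.values[0, 7] == pytest.approx(expected_cross)
        assert ssm.values[0, 2] == pytest.approx(1.0)

    def test_feature_scaling_leaves_ssm_unchanged(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 10))
        g1 = self_similarity(FeatureMatrix("tempo", vals, 4.0)).values
        g2 = self_similarity(FeatureMatrix("tempo", 7.5 * vals, 4.0)).values
        assert np.allclose(g1, g2)

    def test_identical_columns_rejected_by_name(self):
        fm = FeatureMatrix("rhythm", np.ones((4, 6)), 4.0)
        with pytest.raises(ValueError, match="rhythm"):
            self_similarity(fm)


class TestNormalize:
    def test_zero_mean_unit_frobenius(self):
        rng = np.random.default_rng(2)
        d = normalize_matrix(rng.normal(size=(7, 7)))
        assert d.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(d) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=(5, 5))
        assert np.allclose(normalize_matrix(3.0 * d + 2.0), normalize_matrix(d))

    def test_2x2_hand_case(self):
        out = normalize_matrix(np.eye(2))
        assert np.allclose(out, np.array([[0.5, -0.5], [-0.5, 0.5]]))

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        d = normalize_matrix(rng.normal(size=(6, 6)))
        assert np.allclose(normalize_matrix(d), d)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_matrix(np.full((3, 3), 2.0))


def _toy_setup(noise=0.4, seed=0, duration=40.0):
    h = random_hierarchy(SyntheticSpec(duration=duration, depth=2, seed=seed, boundary_rate=4.0))
    feats = planted_features(h, 4.0, noise_scale=noise, seed=seed)
    ssms = {k: self_similarity(v) for k, v in feats.items()}
    m = meet_matrix(sample_labels(h, 4.0))
    return h, m, ssms, feats


class TestCorrelationVector:
    def test_self_correlation_is_one(self):
        _, m, ssms, _ = _toy_setup()
        mhat = normalize_matrix(m.values)
        assert float(np.sum(mhat * mhat)) == pytest.approx(1.0)

    def test_entries_within_unit_interval(self):
        _, m, ssms, _ = _toy_setup()
        z = correlation_vector(m, ssms)
        assert z.shape == (4,)
        assert np.all(np.abs(z) <= 1.0 + 1e-12)

    def test_order_is_tempo_rhythm_chroma_mfcc(self):
        assert FEATURE_KINDS == ("tempo", "rhythm", "chroma", "mfcc")


class TestAnnotationDistance:
    def test_self_distance_zero(self):
        _, m, ssms, _ = _toy_setup()
        assert annotation_distance(m, m, ssms) == pytest.approx(0.0)

    def test_symmetry(self):
        h, m1, ssms, _ = _toy_setup(seed=5)
        h2 = random_hierarchy(SyntheticSpec(duration=40.0, depth=2, seed=6, boundary_rate=4.0))
        m2 = meet_matrix(sample_labels(h2, 4.0, n_frames=m1.n_frames))
        d12 = annotation_distance(m1, m2, ssms)
        d21 = annotation_distance(m2, m1, ssms)
        assert d12 == pytest.approx(d21)
        assert d12 >= 0.0

    def test_identity_whitening_limit_is_squared_euclidean(self):
        """With orthonormal SSMs (W = I), delta reduces to ||z_R - z_E||^2."""
        rng = np.random.default_rng(7)
        n = 8
        # build 4 orthogonal symmetric zero-mean matrices via disjoint
        # symmetric supports
        mats = []
        pairs = [(0, 1), (2, 3), (4, 5), (6, 7)]
        for (i, j), kind in zip(pairs, FEATURE_KINDS):
            m = np.zeros((n, n))
            m[i, j] = m[j, i] = 1.0
            m[i, i] = -1.0
            m[j, j] = -1.0
            m += 0.25  # nonzero mean removed by normalization
            mats.append(SelfSimilarityMatrix(m, 1.0, kind))
        ssms = dict(zip(FEATURE_KINDS, mats))
        w = whitening_gram(ssms)
        assert np.allclose(w, np.eye(4), atol=1e-12)

        from hierseg.hierarchy import MeetMatrix

        m_ref = MeetMatrix(rng.integers(0, 3, size=(n, n)).astype(np.int16), 4.0)
        m_ref = MeetMatrix(np.maximum(m_ref.values, m_ref.values.T), 4.0)
        m_est = MeetMatrix(rng.integers(0, 3, size=(n, n)).astype(np.int16), 4.0)
        m_est = MeetMatrix(np.maximum(m_est.values, m_est.values.T), 4.0)
        diff = correlation_vector(m_ref, ssms) - correlation_vector(m_est, ssms)
        assert annotation_distance(m_ref, m_est, ssms) == pytest.approx(diff @ diff)

    def test_near_singular_gram_falls_back_to_pseudoinverse(self, caplog):
        import logging

        _, m, ssms, _ = _toy_setup(seed=8)
        # all four SSMs identical: W is rank one
        g = ssms["tempo"]
        degenerate = {k: SelfSimilarityMatrix(g.values, g.bandwidth, k) for k in FEATURE_KINDS}
        h2 = random_hierarchy(SyntheticSpec(duration=40.0, depth=2, seed=9, boundary_rate=4.0))
        m2 = meet_matrix(sample_labels(h2, 4.0, n_frames=m.n_frames))
        with caplog.at_level(logging.WARNING, logger="hierseg.correlate"):
            d = annotation_distance(m, m2, degenerate)
        assert d >= 0.0
        assert any("pseudo-inverse" in r.message for r in caplog.records)
        with pytest.raises(np.linalg.LinAlgError):
            annotation_distance(m, m2, degenerate, allow_pseudo_inverse=False)

    def test_delta_depends_only_on_meet_matrices(self):
        # two different hierarchies with identical meet matrices on the grid
        # get delta 0
        _, m, ssms, _ = _toy_setup(seed=10)
        from hierseg.hierarchy import MeetMatrix

        clone = MeetMatrix(m.values.copy(), m.frame_rate)
        assert annotation_distance(m, clone, ssms) == pytest.approx(0.0)

    def test_pipeline_payload(self):
        _, m, ssms, feats = _toy_setup(seed=11)
        out = delta_pipeline(m, m, feats)
        assert out["delta"] == pytest.approx(0.0)
        assert np.allclose(out["z_ref"], out["z_est"])
        assert out["W"].shape == (4, 4)
        assert np.allclose(out["W"], out["W"].T)
        evals = np.linalg.eigvalsh(out["W"])
        assert np.all(evals > -1e-10)
        assert np.allclose(np.diag(out["W"]), 1.0)
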