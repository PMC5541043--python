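"""Data model, validation, file I/O, and frame sampling for structural annotations.

A *flat segmentation* partitions a recording's timeline into contiguous,
labeled intervals.  A *hierarchical segmentation* is an ordered sequence of
flat segmentations, coarse to fine; level 0 — a single segment spanning the
whole track — is logically always present and never stored.

Two on-disk dialects are supported:

* ``interval_lab`` — whitespace-separated ``start end label`` lines, one file
  per level.
* ``salami_boundary`` — ``time<TAB>label`` lines; each segment spans from its
  time to the next line's time, and the final line marks the track end.

Labels are case-sensitive verbatim tokens: ``A``, ``a`` and ``A'`` are three
distinct labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Gaps or overlaps between consecutive intervals up to this many seconds are
#: treated as rounding jitter and snapped to the midpoint on read.
SNAP_TOLERANCE = 0.01

#: Default frame rate (Hz) for metric computation.
METRIC_FRAME_RATE = 10.0

#: Default frame rate (Hz) for the acoustic-correlation (delta) pipeline.
DELTA_FRAME_RATE = 4.0


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Segment:
    """A labeled half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise AnnotationError(
                f"segment must have start < end, got [{self.start}, {self.end})"
            )
        if not self.label.strip():
            raise AnnotationError("segment label must be non-empty")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class FlatSegmentation:
    """An ordered, contiguous, non-overlapping cover of ``[0, duration)``."""

    segments: tuple[Segment, ...]
    duration: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.segments:
            raise AnnotationError("a segmentation must contain at least one segment")
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        duration = self.duration if self.duration else segs[-1].end
        object.__setattr__(self, "duration", float(duration))
        if abs(segs[0].start) > 1e-9:
            raise AnnotationError(f"first segment must start at 0, got {segs[0].start}")
        for prev, cur in zip(segs, segs[1:]):
            if abs(cur.start - prev.end) > 1e-9:
                raise AnnotationError(
                    f"segments must be contiguous: [{prev.start}, {prev.end}) "
                    f"followed by [{cur.start}, {cur.end})"
                )
        if abs(segs[-1].end - self.duration) > 1e-9:
            raise AnnotationError(
                f"last segment ends at {segs[-1].end}, expected duration {self.duration}"
            )

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(s.label for s in self.segments)

    @property
    def boundaries(self) -> np.ndarray:
        """All segment boundary times, including 0 and the track end."""
        return np.array([s.start for s in self.segments] + [self.duration])

    def __len__(self) -> int:
        return len(self.segments)

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[float, float, str]],
        snap_tolerance: float = SNAP_TOLERANCE,
    ) -> "FlatSegmentation":
        """Build a segmentation from (start, end, label) rows, snapping jitter.

        Rows are sorted by start time.  Gaps or overlaps between consecutive
        rows of at most ``snap_tolerance`` seconds are snapped to the midpoint
        of the two conflicting times; anything larger raises
        :class:`AnnotationError`.  A small nonzero first start is snapped to 0.
        """
        rows = sorted(((float(s), float(e), str(lbl)) for s, e, lbl in intervals))
        if not rows:
            raise AnnotationError("no intervals given")
        starts = [r[0] for r in rows]
        ends = [r[1] for r in rows]
        if abs(starts[0]) > snap_tolerance:
            raise AnnotationError(f"first interval starts at {starts[0]}, expected 0")
        starts[0] = 0.0
        for i in range(len(rows) - 1):
            gap = starts[i + 1] - ends[i]
            if abs(gap) > snap_tolerance:
                kind = "gap" if gap > 0 else "overlap"
                raise AnnotationError(
                    f"{kind} of {abs(gap):.4f} s between intervals "
                    f"{i} and {i + 1} exceeds tolerance {snap_tolerance} s"
                )
            mid = 0.5 * (starts[i + 1] + ends[i])
            ends[i] = starts[i + 1] = mid
        segs = tuple(
            Segment(s, e, lbl) for (s, e), lbl in zip(zip(starts, ends), (r[2] for r in rows))
        )
        return cls(segs)


@dataclass(frozen=True)
class Hierarchy:
    """An ordered coarse-to-fine sequence of flat segmentations of one track.

    ``levels[0]`` is the coarsest *stored* level; the implicit whole-track
    level is never stored.  All levels must share the same duration.
    """

    levels: tuple[FlatSegmentation, ...]

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if not levels:
            raise AnnotationError("a hierarchy must contain at least one level")
        d0 = levels[0].duration
        for i, lvl in enumerate(levels):
            if abs(lvl.duration - d0) > 1e-6:
                raise AnnotationError(
                    f"level {i} has duration {lvl.duration}, expected {d0}"
                )

    @property
    def duration(self) -> float:
        return self.levels[0].duration

    @property
    def depth(self) -> int:
        return len(self.levels)

    def truncated(self, duration: float) -> "Hierarchy":
        """Clip every level to ``[0, duration)``, dropping later segments."""
        if duration >= self.duration:
            return self
        new_levels = []
        for lvl in self.levels:
            segs = []
            for s in lvl.segments:
                if s.start >= duration:
                    break
                segs.append(Segment(s.start, min(s.end, duration), s.label))
            new_levels.append(FlatSegmentation(tuple(segs)))
        return Hierarchy(tuple(new_levels))


@dataclass(frozen=True)
class FrameLabelGrid:
    """Per-level integer-coded label sequences on a uniform frame grid.

    Frame ``i`` corresponds to time ``i / frame_rate``.  Integer codes are
    level-local: equal codes across different levels imply nothing.
    """

    frame_rate: float
    labels: np.ndarray  # (depth, n_frames) integer array

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise AnnotationError("labels must be a (depth, n_frames) array")
        object.__setattr__(self, "labels", arr)

    @property
    def depth(self) -> int:
        return int(self.labels.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.labels.shape[1])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_interval_lab(path: Path) -> list[tuple[float, float, str]]:
    rows: list[tuple[float, float, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 2)
            if len(parts) != 3:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 'start end label', got {line!r}"
                )
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad time field: {exc}") from exc
            rows.append((start, end, parts[2]))
    if not rows:
        raise AnnotationError(f"{path}: empty annotation level")
    return rows


def _parse_salami_boundary(path: Path) -> list[tuple[float, float, str]]:
    times: list[float] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(None, 1)
            if len(parts) < 1:
                raise AnnotationError(f"{path}:{lineno}: empty line content")
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad time field: {exc}") from exc
            times.append(t)
            labels.append(parts[1].strip() if len(parts) > 1 else "")
    if len(times) < 2:
        raise AnnotationError(f"{path}: boundary file needs at least two lines")
    rows = []
    for i in range(len(times) - 1):
        if times[i + 1] <= times[i]:
            # zero-length row (repeated boundary time): skip
            continue
        label = labels[i] if labels[i] else "Silence"
        rows.append((times[i], times[i + 1], label))
    if not rows:
        raise AnnotationError(f"{path}: no segments after parsing")
    return rows


_PARSERS = {
    "interval_lab": _parse_interval_lab,
    "salami_boundary": _parse_salami_boundary,
}


def read_annotation(
    source: str | Path | Sequence[str | Path] | Mapping[str, str | Path],
    format: str = "interval_lab",
    levels: Sequence[str] | None = None,
) -> Hierarchy:
    """Read a hierarchical annotation from one file per level.

    Parameters
    ----------
    source
        A single path (depth-1 hierarchy), an ordered sequence of paths
        (coarse to fine), or a mapping of level names to paths.
    format
        One of ``"interval_lab"`` or ``"salami_boundary"``.
    levels
        When ``source`` is a mapping, the level names to keep, in
        coarse-to-fine order.  This is how e.g. a SALAMI ``function`` level is
        dropped.  Ignored for non-mapping sources.
    """
    if format not in _PARSERS:
        raise ValueError(f"unknown annotation format {format!r}")
    parse = _PARSERS[format]

    if isinstance(source, Mapping):
        names = list(levels) if levels is not None else list(source)
        missing = [n for n in names if n not in source]
        if missing:
            raise AnnotationError(f"requested levels not in source: {missing}")
        paths = [Path(source[n]) for n in names]
    elif isinstance(source, (str, Path)):
        paths = [Path(source)]
    else:
        paths = [Path(p) for p in source]

    segmentations = tuple(
        FlatSegmentation.from_intervals(parse(p)) for p in paths
    )
    # Annotator files for the same track can disagree by rounding in the final
    # boundary; reconcile levels to their common minimum span.
    d = min(s.duration for s in segmentations)
    if any(s.duration - d > 1e-6 for s in segmentations):
        return Hierarchy(segmentations).truncated(d)
    return Hierarchy(segmentations)


def write_annotation(
    h: Hierarchy,
    paths: Sequence[str | Path],
    format: str = "interval_lab",
) -> None:
    """Write one file per level, coarse to fine."""
    if len(paths) != h.depth:
        raise ValueError(f"need {h.depth} paths, got {len(paths)}")
    for lvl, path in zip(h.levels, paths):
        with open(path, "w") as fh:
            if format == "interval_lab":
                for s in lvl.segments:
                    fh.write(f"{s.start:.6f}\t{s.end:.6f}\t{s.label}\n")
            elif format == "salami_boundary":
                for s in lvl.segments:
                    fh.write(f"{s.start:.6f}\t{s.label}\n")
                fh.write(f"{lvl.duration:.6f}\tEnd\n")
            else:
                raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Frame sampling
# ---------------------------------------------------------------------------

def _sample_level(level: FlatSegmentation, times: np.ndarray) -> np.ndarray:
    """Integer-coded segment labels at the given times, half-open intervals."""
    starts = np.array([s.start for s in level.segments])
    idx = np.searchsorted(starts, times, side="right") - 1
    idx = np.clip(idx, 0, len(level.segments) - 1)
    labels = [s.label for s in level.segments]
    codes_of = {}
    seg_codes = np.empty(len(labels), dtype=np.int64)
    for i, lbl in enumerate(labels):
        seg_codes[i] = codes_of.setdefault(lbl, len(codes_of))
    return seg_codes[idx]


def sample_labels(
    h: Hierarchy,
    frame_rate: float = METRIC_FRAME_RATE,
    n_frames: int | None = None,
) -> FrameLabelGrid:
    """Sample every level's labels on a uniform grid of ``frame_rate`` Hz.

    Frame ``i`` takes the label of the segment containing time
    ``i / frame_rate`` under the half-open ``[start, end)`` convention; the
    final instant belongs to the last segment.  ``n_frames`` defaults to
    ``ceil(duration * frame_rate)``.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if n_frames is None:
        n_frames = math.ceil(h.duration * frame_rate)
    times = np.arange(n_frames) / frame_rate
    grid = np.vstack([_sample_level(lvl, times) for lvl in h.levels])
    return FrameLabelGrid(frame_rate=frame_rate, labels=grid)


def align_pair(
    h1: Hierarchy,
    h2: Hierarchy,
    frame_rate: float = METRIC_FRAME_RATE,
    tolerance: float = 1.0,
    hard_fail_ratio: float = 2.0,
) -> tuple[FrameLabelGrid, FrameLabelGrid]:
    """Sample two hierarchies of the same recording on a common frame grid.

    Both grids cover ``[0, min(duration1, duration2))``.  A duration mismatch
    above ``tolerance`` seconds logs a warning; a mismatch where the longer
    duration exceeds ``hard_fail_ratio`` times the shorter is an error.  The
    mismatch is resolved by truncation to the shorter annotation — fill labels
    are never invented.
    """
    d1, d2 = h1.duration, h2.duration
    short, long_ = min(d1, d2), max(d1, d2)
    if long_ > hard_fail_ratio * short:
        raise AnnotationError(
            f"durations {d1:.2f} s and {d2:.2f} s differ by more than "
            f"a factor of {hard_fail_ratio}; refusing to compare"
        )
    if abs(d1 - d2) > tolerance:
        logger.warning(
            "annotation durations differ (%.2f s vs %.2f s); truncating to %.2f s",
            d1, d2, short,
        )
    n_frames = math.ceil(short * frame_rate)
    g1 = sample_labels(h1.truncated(short), frame_rate, n_frames=n_frames)
    g2 = sample_labels(h2.truncated(short), frame_rate, n_frames=n_frames)
    return g1, g2
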