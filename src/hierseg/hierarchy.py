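"""Meet matrices, comparison-triple counting, and the L-measure.

The L-measure compares two hierarchical segmentations holistically: instead
of asking whether an annotation labels two instants the *same* or
*different*, it asks whether the pair (t, u) is *more similar* than the pair
(t, v) — i.e. whether (t, u) share a label at a deeper level of the
hierarchy than (t, v) — and whether both annotations respect that ordering.
Because only the rank ordering of meet depths matters, the scores are
invariant to depth alignment errors between annotations (e.g. one
annotator's level 1 matching the other's level 2) and support hierarchies of
different depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .annotations import FrameLabelGrid, Hierarchy, align_pair
from .flat import MetricTriple


@dataclass(frozen=True)
class MeetMatrix:
    """Deepest-common-level matrix of a hierarchy on a frame grid.

    ``values[u, v]`` is the deepest stored level (1-based) at which frames
    ``u`` and ``v`` receive the same label, or 0 when they agree only at the
    implicit whole-track level.  The matrix is symmetric with diagonal equal
    to the stored depth.
    """

    values: np.ndarray  # (T, T) small non-negative integers
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    @property
    def depth(self) -> int:
        return int(self.values.max(initial=0))


class TripleCounts(NamedTuple):
    """Sizes of two comparison sets and their intersection."""

    size_ref: int
    size_est: int
    intersection: int


def meet_matrix(grid: FrameLabelGrid) -> MeetMatrix:
    """Compute the meet matrix of a frame-sampled hierarchy.

    The meet of frames u and v is the maximum stored level index k (1-based)
    whose labels agree at u and v.  Levels need not be nested: the maximum is
    taken over all stored levels independently.  Entry 0 records agreement
    only at the implicit level 0 spanning the whole track.
    """
    if grid.depth < 1:
        raise ValueError("grid must have at least one level")
    T = grid.n_frames
    m = np.zeros((T, T), dtype=np.int16)
    for k in range(grid.depth):
        lab = grid.labels[k]
        np.putmask(m, lab[:, None] == lab[None, :], k + 1)
    return MeetMatrix(values=m, frame_rate=grid.frame_rate)


def _anchor_counts(row_ref: np.ndarray, row_est: np.ndarray, n_ref: int, n_est: int):
    """Concordant / one-sided strict-inequality pair counts for one anchor.

    Given the meet values of all non-anchor frames under each hierarchy,
    counts ordered pairs (u, v) with row[u] > row[v] in the reference, in the
    estimate, and in both, via the joint histogram and cumulative sums.
    """
    joint = np.bincount(
        row_ref.astype(np.int64) * n_est + row_est, minlength=n_ref * n_est
    ).reshape(n_ref, n_est)
    # strictly-less-than counts via inclusive 2-D cumulative sums
    cum = joint.cumsum(axis=0).cumsum(axis=1)
    both = int((joint[1:, 1:] * cum[:-1, :-1]).sum())
    mr = joint.sum(axis=1)
    me = joint.sum(axis=0)
    ref_only = int((mr[1:] * mr.cumsum()[:-1]).sum())
    est_only = int((me[1:] * me.cumsum()[:-1]).sum())
    return ref_only, est_only, both


def triple_counts(m_ref: MeetMatrix, m_est: MeetMatrix) -> TripleCounts:
    """Count the comparison triples of each hierarchy and their intersection.

    A hierarchy's comparison set contains the ordered triples of pairwise
    distinct frames (t, u, v) whose meets satisfy M(t, u) > M(t, v); ties
    contribute to neither set.  Counting is per anchor frame t over the joint
    histogram of meet values — O(T·(T + L_R·L_E)) overall — never by
    enumerating all T³ triples.
    """
    R = m_ref.values
    E = m_est.values
    if R.shape != E.shape:
        raise ValueError(f"meet matrix dimension mismatch: {R.shape} vs {E.shape}")
    T = R.shape[0]
    if T < 3:
        raise ValueError("need at least three frames to form triples")
    n_ref = int(R.max()) + 1
    n_est = int(E.max()) + 1
    keep = ~np.eye(T, dtype=bool)
    size_ref = size_est = inter = 0
    for t in range(T):
        r, e, b = _anchor_counts(R[t][keep[t]], E[t][keep[t]], n_ref, n_est)
        size_ref += r
        size_est += e
        inter += b
    return TripleCounts(size_ref=size_ref, size_est=size_est, intersection=inter)


def triple_counts_bruteforce(m_ref: MeetMatrix, m_est: MeetMatrix) -> TripleCounts:
    """O(T³) reference implementation of :func:`triple_counts`.

    Enumerates all ordered triples of pairwise-distinct frames by broadcast.
    Intended for validation on small grids (T ≲ 60); exercised by the
    ``--oracle`` CLI flag and the test suite.
    """
    R = m_ref.values
    E = m_est.values
    if R.shape != E.shape:
        raise ValueError(f"meet matrix dimension mismatch: {R.shape} vs {E.shape}")
    T = R.shape[0]
    eye = np.eye(T, dtype=bool)
    distinct = (
        ~eye[:, :, None]  # u != t
        & ~eye[:, None, :]  # v != t
        & ~eye[None, :, :]  # u != v
    )
    in_ref = (R[:, :, None] > R[:, None, :]) & distinct
    in_est = (E[:, :, None] > E[:, None, :]) & distinct
    return TripleCounts(
        size_ref=int(in_ref.sum()),
        size_est=int(in_est.sum()),
        intersection=int((in_ref & in_est).sum()),
    )


def l_scores_from_counts(counts: TripleCounts) -> MetricTriple:
    """L-precision, L-recall, and L-measure from triple counts.

    An empty comparison set in a denominator yields score 0 with a warning
    (a hierarchy with no label contrasts offers no ranking evidence).
    """
    if counts.size_est == 0:
        warnings.warn("estimate comparison set is empty; L-precision = 0")
        precision = 0.0
    else:
        precision = counts.intersection / counts.size_est
    if counts.size_ref == 0:
        warnings.warn("reference comparison set is empty; L-recall = 0")
        recall = 0.0
    else:
        recall = counts.intersection / counts.size_ref
    return MetricTriple.from_scores(precision, recall)


def l_scores(
    h_ref: Hierarchy,
    h_est: Hierarchy,
    frame_rate: float = 10.0,
    tolerance: float = 1.0,
) -> MetricTriple:
    """L-precision, L-recall, and L-measure between two hierarchies.

    The hierarchies are sampled on a common ``frame_rate`` grid (truncating
    to the shorter duration when they disagree), converted to meet matrices,
    and compared by counting order-concordant triples.  Swapping the
    arguments exchanges precision and recall.
    """
    g_ref, g_est = align_pair(h_ref, h_est, frame_rate=frame_rate, tolerance=tolerance)
    counts = triple_counts(meet_matrix(g_ref), meet_matrix(g_est))
    return l_scores_from_counts(counts)
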