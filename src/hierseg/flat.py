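"""Flat label-agreement metrics between two frame-sampled segmentations.

Two families are provided, both invariant to bijective relabeling of either
sequence:

* *pairwise classification* — precision/recall over the sets of identically
  labeled pairs of distinct time instants;
* *normalized conditional entropy* (NCE) — over-/under-segmentation scores
  from the joint frame-label distribution.

Each family is summarized by the harmonic mean (F-measure) of its two scores.
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple

import numpy as np

logger = logging.getLogger(__name__)


class MetricTriple(NamedTuple):
    """A (first, second, harmonic-mean) score bundle in [0, 1]³.

    ``first`` is precision (pairwise, L) or the over-segmentation score
    (NCE); ``second`` is recall or the under-segmentation score; ``f`` is
    their harmonic mean, 0 when both components are 0.
    """

    first: float
    second: float
    f: float

    @classmethod
    def from_scores(cls, first: float, second: float) -> "MetricTriple":
        if first + second > 0:
            f = 2.0 * first * second / (first + second)
        else:
            f = 0.0
        return cls(float(first), float(second), float(f))

    @property
    def precision(self) -> float:
        return self.first

    @property
    def recall(self) -> float:
        return self.second


def _as_codes(seq) -> np.ndarray:
    arr = np.asarray(seq)
    _, codes = np.unique(arr, return_inverse=True)
    return codes


def contingency(ref, est) -> np.ndarray:
    """Joint label-count table: entry (i, j) counts frames labeled i in
    ``ref`` and j in ``est``."""
    r = _as_codes(ref)
    e = _as_codes(est)
    if r.shape != e.shape:
        raise ValueError(f"length mismatch: {r.shape[0]} vs {e.shape[0]}")
    nr = int(r.max()) + 1
    ne = int(e.max()) + 1
    return np.bincount(r * ne + e, minlength=nr * ne).reshape(nr, ne)


def _pairs(counts: np.ndarray) -> int:
    """Number of unordered pairs of distinct items within same-label groups."""
    c = counts.astype(np.int64)
    return int((c * (c - 1) // 2).sum())


def pairwise_scores(ref, est) -> MetricTriple:
    """Pairwise classification precision, recall, and F-measure.

    A segmentation's agreement set contains every unordered pair of distinct
    frames that share a label.  Precision is the fraction of the estimate's
    agreement pairs present in the reference's; recall the converse.  Both
    are computed from the joint contingency table in O(|Y_R|·|Y_E|), never by
    materializing pair sets.  A sequence whose labels are all distinct has an
    empty agreement set; the corresponding score is 0 (with a warning).

    Swapping the arguments exchanges precision and recall.
    """
    table = contingency(ref, est)
    if table.sum() < 2:
        raise ValueError("need at least two frames")
    size_ref = _pairs(table.sum(axis=1))
    size_est = _pairs(table.sum(axis=0))
    inter = _pairs(table.ravel())

    if size_est == 0:
        warnings.warn("estimate has no identically labeled frame pairs; precision = 0")
        precision = 0.0
    else:
        precision = inter / size_est
    if size_ref == 0:
        warnings.warn("reference has no identically labeled frame pairs; recall = 0")
        recall = 0.0
    else:
        recall = inter / size_ref
    return MetricTriple.from_scores(precision, recall)


def _conditional_entropy(joint: np.ndarray, axis: int) -> float:
    """H(other | marginal along ``axis``), natural log.

    ``axis=1``: H(est | ref) — sums P[y_r, y_e] * log(P_r[y_r] / P[y_r, y_e]).
    """
    marginal = joint.sum(axis=axis, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(np.broadcast_to(marginal, joint.shape)[nz] / joint[nz])))


def nce_scores(ref, est) -> MetricTriple:
    """Normalized conditional entropy over-/under-segmentation scores.

    The joint distribution of (reference label, estimate label) is estimated
    from frame frequencies.  The over-segmentation score is
    ``1 − H(est | ref) / log |Y_E|`` and the under-segmentation score
    ``1 − H(ref | est) / log |Y_R|``; both are clipped to [0, 1].  When a
    label set is a singleton its maximum entropy is 0 and the normalized term
    is taken as 0, i.e. the score is 1: a one-label estimate cannot be
    over-segmented.  The normalization makes the scores independent of the
    logarithm base.
    """
    table = contingency(ref, est)
    joint = table / table.sum()
    n_ref, n_est = joint.shape

    if n_est <= 1:
        over = 1.0
    else:
        over = 1.0 - _conditional_entropy(joint, axis=1) / np.log(n_est)
    if n_ref <= 1:
        under = 1.0
    else:
        under = 1.0 - _conditional_entropy(joint.T, axis=1) / np.log(n_ref)
    over = float(np.clip(over, 0.0, 1.0))
    under = float(np.clip(under, 0.0, 1.0))
    return MetricTriple.from_scores(over, under)
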