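"""Self-similarity matrices and the whitened annotation distance δ.

Each feature matrix becomes a Gaussian-kernel self-similarity matrix (SSM)
``G[u, v] = exp(−‖X[u] − X[v]‖² / σ)`` whose bandwidth σ is the mean over
frames of the median squared distance to all other frames.  An annotation's
meet matrix M is correlated against each SSM by the Frobenius inner product
of mean-centered, unit-Frobenius-norm matrices, giving a 4-vector z(M) of
feature correlations in [−1, 1] (tempo, rhythm, chroma, MFCC order).

The distance between two annotations of the same recording is the quadratic
form δ = (z_R − z_E)ᵀ W⁻¹ (z_R − z_E), where W is the Gram matrix of the
normalized SSMs.  Whitening by W⁻¹ discounts directions in which the
acoustic features are mutually correlated, so δ measures genuine divergence
in which features each annotation tracks.  δ is symmetric, non-negative, and
depends on the annotations only through their meet matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .features import FEATURE_KINDS, FeatureMatrix
from .hierarchy import MeetMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelfSimilarityMatrix:
    """Gaussian-kernel similarity between all pairs of feature frames."""

    values: np.ndarray
    bandwidth: float
    kind: str

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])


def self_similarity(x: FeatureMatrix) -> SelfSimilarityMatrix:
    """Gaussian-kernel SSM of a feature matrix.

    The bandwidth is σ = mean_u median_v ‖X[u] − X[v]‖², which makes the
    kernel invariant to uniform rescaling of the features.  A feature whose
    frames are all identical has σ = 0 and is rejected.
    """
    if x.n_frames < 2:
        raise ValueError("need at least two frames for a self-similarity matrix")
    d2 = squareform(pdist(x.values.T, metric="sqeuclidean"))
    sigma = float(np.mean(np.median(d2, axis=1)))
    if sigma <= 0.0:
        raise ValueError(
            f"degenerate {x.kind} features: all frames identical (sigma = 0)"
        )
    return SelfSimilarityMatrix(np.exp(-d2 / sigma), sigma, x.kind)


def normalize_matrix(d: np.ndarray) -> np.ndarray:
    """Center a square matrix to zero mean and scale to unit Frobenius norm."""
    d = np.asarray(d, dtype=np.float64)
    centered = d - d.mean()
    norm = np.linalg.norm(centered)
    if norm <= 1e-300:
        raise ValueError("cannot normalize a constant matrix")
    return centered / norm


def _ordered_ssms(ssms: dict[str, SelfSimilarityMatrix]) -> list[SelfSimilarityMatrix]:
    missing = [k for k in FEATURE_KINDS if k not in ssms]
    if missing:
        raise ValueError(f"missing self-similarity matrices for: {missing}")
    return [ssms[k] for k in FEATURE_KINDS]


def correlation_vector(
    m: MeetMatrix, ssms: dict[str, SelfSimilarityMatrix]
) -> np.ndarray:
    """z(M): Frobenius correlations of a meet matrix with the four SSMs.

    Both operands are normalized (zero mean, unit Frobenius norm), so each
    entry lies in [−1, 1] by Cauchy–Schwarz.  Order: tempo, rhythm, chroma,
    MFCC.
    """
    mhat = normalize_matrix(m.values)
    z = np.empty(len(FEATURE_KINDS))
    for i, ssm in enumerate(_ordered_ssms(ssms)):
        if ssm.values.shape != mhat.shape:
            raise ValueError(
                f"{ssm.kind} SSM is {ssm.values.shape}, meet matrix is {mhat.shape}"
            )
        z[i] = float(np.sum(mhat * normalize_matrix(ssm.values)))
    return z


def whitening_gram(ssms: dict[str, SelfSimilarityMatrix]) -> np.ndarray:
    """W: 4×4 Gram matrix of Frobenius inner products of normalized SSMs."""
    normalized = [normalize_matrix(s.values) for s in _ordered_ssms(ssms)]
    n = len(normalized)
    w = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            w[i, j] = w[j, i] = float(np.sum(normalized[i] * normalized[j]))
    return w


def annotation_distance(
    m_ref: MeetMatrix,
    m_est: MeetMatrix,
    ssms: dict[str, SelfSimilarityMatrix],
    allow_pseudo_inverse: bool = True,
    rcond: float = 1e-8,
) -> float:
    """Whitened distance δ between two annotations' meet matrices.

    δ = (z_R − z_E)ᵀ W⁻¹ (z_R − z_E).  When W is singular or near-singular
    (highly correlated SSMs) and ``allow_pseudo_inverse`` is set, the
    Moore–Penrose pseudo-inverse with relative cutoff ``rcond`` is used and
    a warning logged; otherwise the error propagates.
    """
    diff = correlation_vector(m_ref, ssms) - correlation_vector(m_est, ssms)
    w = whitening_gram(ssms)
    cond = np.linalg.cond(w)
    if cond > 1.0 / rcond:
        if not allow_pseudo_inverse:
            raise np.linalg.LinAlgError(
                f"whitening Gram matrix is near-singular (cond = {cond:.3g})"
            )
        logger.warning(
            "whitening Gram matrix near-singular (cond = %.3g); using pseudo-inverse",
            cond,
        )
        winv = np.linalg.pinv(w, rcond=rcond)
        return float(diff @ winv @ diff)
    return float(diff @ np.linalg.solve(w, diff))


def delta_pipeline(
    meet_ref: MeetMatrix,
    meet_est: MeetMatrix,
    features: dict[str, FeatureMatrix],
) -> dict:
    """Full δ computation from prepared 4 Hz features and two meet matrices.

    Returns a dict with the two z-vectors, the whitening Gram matrix W, and
    δ — the payload the ``delta`` CLI command serializes.
    """
    ssms = {k: self_similarity(v) for k, v in features.items()}
    z_ref = correlation_vector(meet_ref, ssms)
    z_est = correlation_vector(meet_est, ssms)
    return {
        "z_ref": z_ref,
        "z_est": z_est,
        "W": whitening_gram(ssms),
        "delta": annotation_distance(meet_ref, meet_est, ssms),
    }
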