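"""Corpus-scale evaluation: all-pairs annotator scores, quadrant/median
analysis, distribution comparison, and bootstrap confidence intervals.

A corpus manifest (JSON or YAML) lists, per track, one annotation per
annotator, each annotation being an ordered list of per-level files::

    {
      "format": "interval_lab",
      "tracks": {
        "track01": {
          "ann1": ["track01.ann1.upper.lab", "track01.ann1.lower.lab"],
          "ann2": ["track01.ann2.upper.lab", "track01.ann2.lower.lab"]
        }
      }
    }

Relative paths resolve against the manifest's directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .annotations import Hierarchy, read_annotation, sample_labels, align_pair
from .flat import nce_scores, pairwise_scores
from .hierarchy import l_scores

logger = logging.getLogger(__name__)

LEVEL_NAMES = ("upper", "lower")


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    manifest = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    manifest.setdefault("format", "interval_lab")
    manifest["_root"] = path.parent
    return manifest


def _load_track(entry: Mapping[str, Sequence[str]], fmt: str, root: Path) -> dict[str, Hierarchy]:
    out = {}
    for annotator, files in entry.items():
        paths = [root / f for f in ([files] if isinstance(files, str) else files)]
        out[annotator] = read_annotation(paths, format=fmt)
    return out


def pair_scores(
    h1: Hierarchy,
    h2: Hierarchy,
    frame_rate: float = 10.0,
) -> dict[tuple[str, str], float]:
    """All metrics for one annotation pair: the L triple, per-level pairwise
    and NCE triples, and the across-level max/min of the pairwise F-measure.

    Keys are (metric, level) tuples; the level is ``"all"`` for L scores and
    the across-level summaries.
    """
    rows: dict[tuple[str, str], float] = {}
    l = l_scores(h1, h2, frame_rate=frame_rate)
    rows[("l_precision", "all")] = l.first
    rows[("l_recall", "all")] = l.second
    rows[("l_measure", "all")] = l.f

    g1, g2 = align_pair(h1, h2, frame_rate=frame_rate)
    depth = min(g1.depth, g2.depth)
    pw_fs = []
    for k in range(depth):
        name = LEVEL_NAMES[k] if k < len(LEVEL_NAMES) else f"level{k + 1}"
        pw = pairwise_scores(g1.labels[k], g2.labels[k])
        nce = nce_scores(g1.labels[k], g2.labels[k])
        rows[("pairwise_precision", name)] = pw.first
        rows[("pairwise_recall", name)] = pw.second
        rows[("pairwise_f", name)] = pw.f
        rows[("nce_over", name)] = nce.first
        rows[("nce_under", name)] = nce.second
        rows[("nce_f", name)] = nce.f
        pw_fs.append(pw.f)
    rows[("pairwise_f_max", "all")] = max(pw_fs)
    rows[("pairwise_f_min", "all")] = min(pw_fs)
    return rows


def corpus_scores(
    manifest: str | Path | Mapping,
    frame_rate: float = 10.0,
) -> pd.DataFrame:
    """Score every unordered annotator pair of every track in a corpus.

    Returns a tidy frame with columns (track, annotator_a, annotator_b,
    metric, level, value).  A track with five annotators contributes all ten
    pairs.  Tracks whose annotations fail to load are skipped with a logged
    warning.  Output is sorted, so manifest ordering does not matter.
    """
    if not isinstance(manifest, Mapping):
        manifest = load_manifest(manifest)
    fmt = manifest.get("format", "interval_lab")
    root = Path(manifest.get("_root", "."))
    records = []
    for track_id in sorted(manifest["tracks"]):
        try:
            anns = _load_track(manifest["tracks"][track_id], fmt, root)
        except Exception as exc:  # noqa: BLE001 - corpus runs must not abort
            logger.warning("skipping track %s: %s", track_id, exc)
            continue
        for a, b in combinations(sorted(anns), 2):
            for (metric, level), value in pair_scores(
                anns[a], anns[b], frame_rate=frame_rate
            ).items():
                records.append((track_id, a, b, metric, level, value))
    return pd.DataFrame(
        records,
        columns=["track", "annotator_a", "annotator_b", "metric", "level", "value"],
    )


@dataclass(frozen=True)
class QuadrantSummary:
    """Quadrant fractions of a paired score sample around its medians.

    Quadrants follow the plotting convention: I is (x > median_x,
    y > median_y), II is upper-left, III lower-left, IV lower-right.  Points
    on a median line are assigned to the lower (≤) side of that axis.
    ``conditional`` holds the two fractions of interest for rank agreement:
    ``below_y_given_below_x`` = III / (II + III) and
    ``above_y_given_above_x`` = I / (I + IV).
    """

    median_x: float
    median_y: float
    fractions: dict[str, float]
    conditional: dict[str, float]
    n: int


def quadrant_analysis(x, y) -> QuadrantSummary:
    """Split a paired sample into quadrants along the per-axis medians."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if x.size < 2:
        raise ValueError("need at least two points")
    mx, my = float(np.median(x)), float(np.median(y))
    hi_x, hi_y = x > mx, y > my
    counts = {
        "I": int(np.sum(hi_x & hi_y)),
        "II": int(np.sum(~hi_x & hi_y)),
        "III": int(np.sum(~hi_x & ~hi_y)),
        "IV": int(np.sum(hi_x & ~hi_y)),
    }
    n = x.size
    left = counts["II"] + counts["III"]
    right = counts["I"] + counts["IV"]
    conditional = {
        "below_y_given_below_x": counts["III"] / left if left else float("nan"),
        "above_y_given_above_x": counts["I"] / right if right else float("nan"),
    }
    return QuadrantSummary(
        median_x=mx,
        median_y=my,
        fractions={k: v / n for k, v in counts.items()},
        conditional=conditional,
        n=n,
    )


def ks_statistic(a, b) -> float:
    """Two-sample Kolmogorov–Smirnov statistic.

    The maximum absolute difference between the two empirical cumulative
    distribution functions: 0 for identical samples, 1 for samples with
    disjoint supports.  Invariant under any common strictly monotone
    transform of both samples.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(scipy.stats.ks_2samp(a, b, method="asymp").statistic)


_STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": np.mean,
    "median": np.median,
    "std": np.std,
}


def bootstrap_ci(
    values,
    statistic: str | Callable[[np.ndarray], float] = "mean",
    trials: int = 500,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for a summary statistic.

    Resamples with replacement ``trials`` times and returns the central
    ``level`` percentile interval.  Deterministic under a fixed seed.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty sample")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.integers(0, values.size, size=(trials, values.size))
    if isinstance(statistic, str):
        boot = _STATISTICS[statistic](values[idx], axis=1)
    else:
        boot = np.array([statistic(values[row]) for row in idx])
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(boot, [alpha, 100.0 - alpha])
    return float(lo), float(hi)
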