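"""Corpus-scale evaluation on a synthetic multi-annotator corpus.

Generates 40 tracks with two annotator views each, scores every pair,
and summarizes how the L-measure relates to the best per-level flat
F-measure via median-quadrant analysis, with a bootstrap confidence
interval for the mean L-measure and a KS comparison between two halves of
the corpus.
"""

import numpy as np

from hierseg import bootstrap_ci, ks_statistic, pair_scores, quadrant_analysis
from hierseg.synthetic import SyntheticSpec, synthetic_corpus

tracks = synthetic_corpus(40, seed=5, spec=SyntheticSpec(duration=90.0, boundary_rate=2.0))

l_measures, f_maxes = [], []
for _, view_a, view_b in tracks:
    rows = pair_scores(view_a, view_b, frame_rate=10.0)
    l_measures.append(rows[("l_measure", "all")])
    f_maxes.append(rows[("pairwise_f_max", "all")])

quad = quadrant_analysis(f_maxes, l_measures)
print(f"median max-F = {quad.median_x:.3f}, median L = {quad.median_y:.3f}")
print("quadrant fractions:", {k: round(v, 3) for k, v in quad.fractions.items()})
print(
    "of the pairs below the median max-F, "
    f"{100 * quad.conditional['below_y_given_below_x']:.0f}% lie below the median L"
)

lo, hi = bootstrap_ci(l_measures, "mean", trials=500, seed=6)
print(f"mean L = {np.mean(l_measures):.3f}, 95% bootstrap CI [{lo:.3f}, {hi:.3f}]")

first, second = l_measures[:20], l_measures[20:]
print(f"KS between corpus halves: {ks_statistic(first, second):.3f}")

print(
    "\nA large below-median overlap shows the L-measure broadly agreeing"
    "\nwith level-wise comparison while still integrating cross-level"
    "\nstructure the flat scores cannot see."
)
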