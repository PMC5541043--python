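"""The 4-frame worked example behind the L-measure, step by step.

Two tiny two-level hierarchies are sampled on 4 frames; we print their meet
matrices (the deepest level at which each frame pair shares a label), count
the order-concordant triples, and derive the L-scores.
"""

import numpy as np

from hierseg import (
    FrameLabelGrid,
    l_scores_from_counts,
    meet_matrix,
    triple_counts,
    triple_counts_bruteforce,
)

# reference: levels (A A B B) and (a b c c); estimate: (A A A B), (a a b b)
g_ref = FrameLabelGrid(10.0, np.array([[0, 0, 1, 1], [0, 1, 2, 2]]))
g_est = FrameLabelGrid(10.0, np.array([[0, 0, 0, 1], [0, 0, 1, 1]]))

m_ref, m_est = meet_matrix(g_ref), meet_matrix(g_est)
print("reference meet matrix:\n", m_ref.values)
print("estimate meet matrix:\n", m_est.values)

counts = triple_counts(m_ref, m_est)
print(f"\n|A(ref)| = {counts.size_ref}, |A(est)| = {counts.size_est}, "
      f"|A(ref) ∩ A(est)| = {counts.intersection}")
assert counts == triple_counts_bruteforce(m_ref, m_est)

triple = l_scores_from_counts(counts)
print(f"L-precision = {triple.first:.3f}  (= {counts.intersection}/{counts.size_est})")
print(f"L-recall    = {triple.second:.3f}  (= {counts.intersection}/{counts.size_ref})")
print(f"L-measure   = {triple.f:.3f}  (harmonic mean)")

print(
    "\nEach triple (t, u, v) counts when (t, u) share a label at a deeper"
    "\nlevel than (t, v); the L-scores compare which of those rank orderings"
    "\nthe two annotations have in common."
)
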