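"""Acoustic-correlation distance δ between two annotations.

Plants a hierarchy, synthesizes feature matrices whose self-similarity
follows its structure, and compares two perturbed annotator views: each view
gets a 4-vector z of correlations between its meet matrix and the four
feature self-similarity matrices (tempo, rhythm, chroma, MFCC order), and δ
is the whitened squared distance between the z-vectors.
"""

import numpy as np

from hierseg import (
    FrameLabelGrid,
    align_pair,
    delta_pipeline,
    l_scores,
    meet_matrix,
)
from hierseg.synthetic import SyntheticSpec, perturb, planted_features, random_hierarchy

planted = random_hierarchy(SyntheticSpec(duration=120.0, depth=2, seed=10, boundary_rate=3.0))
view_a = perturb(planted, "jitter_boundaries", 1.0, seed=11)
view_b = perturb(perturb(planted, "relabel_noise", 0.4, seed=12), "jitter_boundaries", 3.0, seed=13)

features = planted_features(planted, frame_rate=4.0, noise_scale=0.5, seed=14)
g_a, g_b = align_pair(view_a, view_b, frame_rate=4.0)
n = features["tempo"].n_frames
m_a = meet_matrix(FrameLabelGrid(4.0, g_a.labels[:, :n]))
m_b = meet_matrix(FrameLabelGrid(4.0, g_b.labels[:, :n]))

result = delta_pipeline(m_a, m_b, features)
np.set_printoptions(precision=2, suppress=True)
print("z (view A):", result["z_ref"], " order: tempo, rhythm, chroma, mfcc")
print("z (view B):", result["z_est"])
print("whitening Gram W:\n", result["W"])
print(f"delta = {result['delta']:.3f}")
print(f"L-measure = {l_scores(view_a, view_b).f:.3f}")

print(
    "\nA small δ means both annotations correlate with the same acoustic"
    "\nfeatures; δ rises — and the L-measure falls — as the two views drift"
    "\napart from the planted structure."
)
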