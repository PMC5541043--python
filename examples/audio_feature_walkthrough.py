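"""The four acoustic feature extractors on synthesized audio.

Builds a 10-second signal whose first half is a click track over an A-major
arpeggio and whose second half is faster clicks over noise, then extracts
tempo, rhythm, chroma, and MFCC features and shows that their self-
similarity matrices separate the two halves.
"""

import numpy as np

from hierseg import extract_all, prepare_features, self_similarity

SR = 22_050
rng = np.random.default_rng(0)


def clicks(period_s: float, n: int) -> np.ndarray:
    y = np.zeros(n)
    for i in range(0, n, int(SR * period_s)):
        y[i : i + 64] = 1.0
    return y


n_half = SR * 5
tones = sum(np.sin(2 * np.pi * f * np.arange(n_half) / SR) for f in (220.0, 277.2, 329.6))
first = clicks(0.5, n_half) + 0.2 * tones
second = clicks(0.25, n_half) + 0.2 * rng.normal(size=n_half)
y = np.concatenate([first, second])

features = extract_all(y)
for kind, fm in features.items():
    print(f"{kind}: {fm.values.shape[0]} x {fm.n_frames} at {fm.frame_rate:.1f} Hz")

prepared = prepare_features(features, duration=len(y) / SR)
print("\nafter 4 Hz down-sampling and time-delay embedding:")
for kind, fm in prepared.items():
    print(f"{kind}: {fm.values.shape[0]} x {fm.n_frames}")

print("\nwithin- vs cross-half mean self-similarity:")
for kind, fm in prepared.items():
    g = self_similarity(fm).values
    half = fm.n_frames // 2
    within = (g[:half, :half].mean() + g[half:, half:].mean()) / 2
    cross = g[:half, half:].mean()
    print(f"{kind}: within = {within:.2f}, cross = {cross:.2f}")

print(
    "\nEvery descriptor is more self-similar within a homogeneous half than"
    "\nacross the change point — the block structure annotations are"
    "\ncorrelated against."
)
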