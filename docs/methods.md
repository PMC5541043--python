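# Methods

This note records the models, conventions, and numerical choices behind
`hierseg`, and what the synthetic fixtures do and do not establish.

## Data model and frame sampling

A flat segmentation is a contiguous, non-overlapping cover of
`[0, duration)` by labeled half-open intervals `[start, end)`; boundary
instants belong to the segment on their right.  A hierarchy is an ordered
coarse-to-fine tuple of such segmentations sharing one duration; the
implicit level 0 (a single whole-track segment) is never stored but always
participates in meet computations, which guarantees every frame pair meets
somewhere while never contributing ranking contrasts of its own.

All metrics operate on frame-sampled label grids.  Frame `i` takes the
label at time `i / frame_rate`, and `n_frames = ceil(duration ×
frame_rate)`.  Defaults: **10 Hz** for the agreement metrics and **4 Hz**
for the acoustic-correlation pipeline (self-similarity matrices are T×T,
and 4 Hz keeps a five-minute track near 1,200 frames); both are arguments
everywhere.

Annotation files carry rounding jitter; gaps or overlaps of at most
0.01 s between consecutive intervals are snapped to the midpoint, larger
ones are errors.  When two annotations of one track disagree in duration,
both are truncated to the shorter before sampling — truncation never
fabricates agreement, whereas any fill label would.  Mismatches beyond a
tolerance (default 1 s) log a warning; beyond a hard ratio (default 2×)
they are errors.  Labels are verbatim case-sensitive tokens: variant
markers such as `A'` are distinct labels, and the metrics are accordingly
blind to the variant relationship — a known limitation shared with all
label-agreement metrics of this family (as is the inability to distinguish
`aa` from a single `A` span).

## Flat metrics

Pairwise classification scores are computed from the joint label
contingency table: a segmentation's agreement set size is
`Σ_y C(c_y, 2)` over its label counts and the intersection is
`Σ_{ij} C(n_ij, 2)` over joint counts — identical to enumerating unordered
pairs of distinct frames but O(|Y_R|·|Y_E|).  A sequence with all-distinct
labels has an empty agreement set; the affected score is 0 with a warning.

The conditional entropy `H(P_E | P_R) = Σ P[y_r, y_e] log(P_R[y_r] /
P[y_r, y_e])` is normalized by `log |Y_E|` and subtracted from 1 (and
symmetrically for under-segmentation).  Natural logarithms are used; the
normalization cancels the base.  When a label set is a singleton its
maximum entropy is zero, and we define the normalized term as 0 (score 1):
a one-label estimate cannot be over-segmented.  This convention is ours —
it is declared, not inherited — and matters only for degenerate
annotations.  Scores are clipped to [0, 1].

## L-measure

Meet matrices are built by overwriting, in ascending level order, the
entries of each level's label-equality mask with the level index; levels
need not be nested (the meet is a max over levels).  Values are stored as
int16: a 5-minute track at 10 Hz is a 3,000² matrix, 18 MB.

Triple counting follows the strict-inequality definition verbatim on both
hierarchies: ordered triples `(t, u, v)` of pairwise-distinct frames with
`M(t,u) > M(t,v)`; ties contribute to neither comparison set.  Per anchor
`t`, the joint histogram `J[i, j]` of (reference meet, estimate meet)
values over all other frames yields the concordant count as
`Σ J[i,j] · C[i−1, j−1]` with `C` the 2-D inclusive cumulative sum, and
the per-hierarchy set sizes from the marginals — O(T·(T + L_R·L_E))
overall.  An O(T³) broadcast enumerator (`triple_counts_bruteforce`) is
kept as an independent cross-check and behind the CLI `--oracle` flag.

An empty comparison set (a hierarchy whose levels carry a single label
each, hence no ranking evidence) makes the corresponding score 0 with a
warning; such annotations genuinely occur in multi-annotator corpora.

Invariances verified by the test suite: bijective relabeling per level,
exact level duplication, any strictly monotone transform of one
hierarchy's meet values, and perfect L-recall of any refinement that
subdivides deepest segments under fresh labels.

## Acoustic features

All extractors consume 22,050 Hz mono audio on a hop-512 (~43 Hz) frame
grid and are implemented on numpy/scipy:

* **Mel spectrogram** — 2048-point Hann STFT with centered zero-padded
  frames; 128 triangular filters on the HTK mel scale (`2595·log10(1 +
  f/700)`) up to 11,025 Hz; log-power as `10·log10` with a 1e−10 (−100 dB)
  floor.
* **Onset strength** — mean over mel bands of the half-wave-rectified
  first time difference of the log-power mel spectrogram, zero-prepended
  to preserve frame count.
* **Tempo (384 × T)** — per-frame autocorrelation of the onset envelope
  over centered 384-frame (~8.9 s) Hann windows, lags 0–383, computed by
  zero-padded FFT; each column peak-normalized, all-zero columns left as
  zeros.
* **Rhythm (33 × T)** — scale (Mellin) transform magnitude of each tempo
  column: linear interpolation onto a geometric lag grid from t₀ = 0.5 to
  384 frames with 128 points (a power of two ≥ 2n), multiplication by
  √lag — the `e^{ξ/2}` factor of the Mellin kernel on the log-lag axis ξ,
  which is what renders the magnitude invariant to multiplicative lag
  scaling — then the real FFT, keeping the ⌊64/2⌋+1 = 33 lowest
  non-negative scale bins, and log-power last.  Without the kernel factor
  the oversampled near-zero-lag region (common to all signals) dominates
  and the tempo-invariance property of the descriptor degrades markedly.
* **Chroma (12 × T)** — a 4096-point STFT whose bins are assigned to the
  nearest of 36-per-octave log-frequency bins spanning C1–C8, with each
  semitone's three bins folded into its pitch class and each frame
  peak-normalized.  This is a constant-Q *binning* of a fixed-resolution
  transform rather than a multi-resolution constant-Q transform; at the
  lowest octave the FFT's 5.4 Hz bin spacing under-resolves semitones,
  which is acceptable for the correlation use here.
* **MFCC (20 × T)** — orthonormal type-II DCT of the log-power mel
  spectrogram, first 20 coefficients.

For the correlation pipeline all features are linearly interpolated onto a
shared 4 Hz grid (`ceil(duration × 4)` frames); chroma and MFCC are
time-delay embedded with their two previous frames (12→36, 20→60 rows;
leading frames pad by repetition) to stabilize local similarity, while the
long-window tempo and rhythm features are not.

## Self-similarity, z-vectors, and δ

`G[u,v] = exp(−‖X[u]−X[v]‖²/σ)` with `σ = mean_u median_v ‖X[u]−X[v]‖²`,
which makes G invariant to uniform feature rescaling; identical-column
feature matrices are rejected by name.  Matrices entering correlations are
standardized once to zero mean and unit Frobenius norm (the operation is
idempotent and errors on constant matrices — notably the meet matrix of a
single-label annotation, which carries no structure to correlate).

`z(M)` collects the Frobenius inner products of the normalized meet matrix
with the four normalized SSMs in (tempo, rhythm, chroma, MFCC) order; each
entry lies in [−1, 1].  The annotation distance is the quadratic form
`δ = (z_R − z_E)ᵀ W⁻¹ (z_R − z_E)` with `W[i,j] = ⟨Ĝ_i, Ĝ_j⟩`; whitening
discounts directions in which the features are mutually correlated.  δ is
symmetric and non-negative, and depends on the annotations only through
their meet matrices.  Since the four SSMs are often highly correlated, W
can be ill-conditioned; when its condition number exceeds 1e8 the
Moore–Penrose pseudo-inverse (relative cutoff 1e−8) is used and a warning
logged, or an error raised if the fallback is disabled.

## Corpus evaluation

`corpus_scores` scores every unordered annotator pair per track (10 pairs
for a five-annotator track) with the L triple, per-level pairwise and NCE
triples, and the across-level max/min of the pairwise F-measure, emitting
a tidy table; unreadable tracks are skipped with a logged warning and
ordering of the manifest is immaterial.  Quadrant analysis splits a paired
sample along the two medians, assigns points on a median line to the lower
side, and reports unconditional fractions plus the two conditional
fractions (share of below-x points that are also below-y, and of above-x
points also above-y) used to summarize rank agreement between metrics.
The two-sample KS statistic delegates to `scipy.stats.ks_2samp`; the
bootstrap returns seeded percentile intervals (default 95%, 500 trials).

## Synthetic fixtures

`random_hierarchy` draws interior boundaries per level from a Poisson
process at `boundary_rate` per minute (default 2.0 — about seven coarse
sections in a three-minute track, comparable to a pop-song annotation),
labels uniformly from a per-level alphabet (default 5 symbols, adjacent
repeats allowed), and by default nests deeper levels by subdividing parent
segments; a non-nested mode draws levels independently to exercise the
max-over-levels meet.  Boundaries closer than 0.5 s to a neighbor are
dropped for realism, which biases segment counts slightly below the
Poisson mean (the test allows for this).  Perturbations (label
permutation, level duplication, refinement, boundary jitter, label noise)
are seeded and deterministic.

`planted_features` maps each deepest-level label to a random Gaussian
prototype column per feature kind (dimensions matching the prepared
extractors: 384/33/36/60) and adds isotropic noise, emulating the block
structure real SSMs exhibit for structured audio.  `synthetic_corpus`
derives two annotator views per track by perturbing a planted hierarchy
with track-varying strength, redrawing the rare tracks where a hierarchy
degenerates to a single label at some level.

These fixtures establish the *metric* properties (oracle equivalence,
invariances, the sign of the δ–L relationship) but deliberately do not
imitate real annotator behavior: no genre- or annotator-specific styles,
no systematic over-/under-segmentation biases, and feature prototypes are
ideal blocks rather than the diagonal-streaked similarity structure real
chroma exhibits.  Passing tests therefore demonstrate correctness of the
computations and the qualitative behavior of the measures, not
quantitative agreement with any particular corpus.  Problem sizes used by
the default test run and the acceptance script — grids up to T = 40
against brute force, 100-case invariance sweeps of 20–50 s tracks, a
50-track planted corpus of 90 s tracks — were chosen so the qualitative
conclusions are stable across seeds.

## Known limitations

* Audio I/O reads WAV via `scipy.io.wavfile` (any sample rate, resampled
  with `resample_poly`); compressed formats are out of scope.
* The scale-transform resampling density, mel-scale variant, spectral-flux
  construction, and log floor are package conventions where several
  reasonable choices exist; z and δ values on real audio may shift at the
  second decimal under different conventions.
* NCE's singleton-label convention is a declared choice (see above).
* Scores depend on the sampling rate of the frame grid; 10 Hz (metrics)
  and 4 Hz (δ) are the defaults used throughout.
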