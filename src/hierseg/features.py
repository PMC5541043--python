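"""Acoustic feature extractors for the annotation–audio correlation pipeline.

Four descriptors are computed from 22,050 Hz mono audio, all on a common
~43 Hz frame grid (hop 512 samples):

* **tempo** — short-time autocorrelation of the onset strength envelope over
  centered 384-frame Hann windows (384 × T).  Peaks at lag ℓ indicate onsets
  recurring every ℓ frames, i.e. the local tempo.
* **rhythm** — log-power magnitude of the scale (Mellin) transform of each
  tempo column (33 × T).  Resampling the autocorrelation on a logarithmic
  lag axis turns tempo changes into shifts, which the Fourier magnitude
  discards, giving an approximately tempo-invariant rhythm descriptor.
* **chroma** — log-frequency (constant-Q-binned, 36 bins/octave, C1–C8)
  spectrogram energy folded into 12 pitch classes, per-frame peak-normalized
  (12 × T).
* **mfcc** — first 20 Mel-frequency cepstral coefficients of a 128-band
  log-power Mel spectrogram (20 × T).

:func:`prepare_features` then resamples everything to 4 Hz and time-delay
embeds chroma and MFCC, producing the matrices the self-similarity stage
consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.fft
import scipy.io.wavfile
import scipy.signal

SAMPLE_RATE = 22_050
HOP_LENGTH = 512
N_FFT = 2048
N_MELS = 128
TEMPO_WINDOW = 384          # autocorrelation window / max lag, in frames
SCALE_T0 = 0.5              # minimum lag of the log-lag grid, fractional frames
SCALE_BINS = 64             # scale bins n; kept rows = n//2 + 1 = 33
LOG_FLOOR = 1e-10           # −100 dB power floor keeping zeros finite

FEATURE_KINDS = ("tempo", "rhythm", "chroma", "mfcc")

#: Feature dimensionality after :func:`prepare_features` (post-embedding).
PREPARED_DIMS = {"tempo": 384, "rhythm": 33, "chroma": 36, "mfcc": 60}


@dataclass(frozen=True)
class FeatureMatrix:
    """A d × T acoustic descriptor matrix on a uniform frame grid."""

    kind: str
    values: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("feature values must be a (d, T) matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.kind} features contain non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[1])


# ---------------------------------------------------------------------------
# Audio loading and spectrogram plumbing
# ---------------------------------------------------------------------------

def load_audio(path: str | Path, sr: int = SAMPLE_RATE) -> tuple[np.ndarray, int]:
    """Load a WAV file as float mono, resampled to ``sr``."""
    in_sr, data = scipy.io.wavfile.read(path)
    y = np.asarray(data, dtype=np.float64)
    if np.issubdtype(np.asarray(data).dtype, np.integer):
        y = y / float(np.iinfo(np.asarray(data).dtype).max)
    if y.ndim > 1:
        y = y.mean(axis=1)
    if in_sr != sr:
        g = math.gcd(in_sr, sr)
        y = scipy.signal.resample_poly(y, sr // g, in_sr // g)
    return y, sr


def frame_times(n_frames: int, sr: int = SAMPLE_RATE, hop: int = HOP_LENGTH) -> np.ndarray:
    return np.arange(n_frames) * hop / sr


def _frame_signal(y: np.ndarray, frame_length: int, hop: int) -> np.ndarray:
    """Centered frames with zero padding; one frame per hop of the input."""
    if y.size == 0:
        raise ValueError("empty signal")
    n_frames = 1 + len(y) // hop
    pad = frame_length // 2
    ypad = np.concatenate([np.zeros(pad), y, np.zeros(pad + frame_length)])
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return ypad[idx]


def stft_magnitude(y: np.ndarray, n_fft: int = N_FFT, hop: int = HOP_LENGTH) -> np.ndarray:
    """Magnitude STFT, (1 + n_fft/2) × T, centered Hann frames."""
    frames = _frame_signal(y, n_fft, hop)
    window = scipy.signal.get_window("hann", n_fft, fftbins=True)
    return np.abs(np.fft.rfft(frames * window, axis=1)).T


def mel_filterbank(
    n_mels: int = N_MELS,
    n_fft: int = N_FFT,
    sr: int = SAMPLE_RATE,
    fmin: float = 0.0,
    fmax: float = SAMPLE_RATE / 2,
) -> np.ndarray:
    """Triangular Mel filterbank (HTK mel scale), n_mels × (1 + n_fft/2)."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = mel_pts[i], mel_pts[i + 1], mel_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def _log_power(x: np.ndarray) -> np.ndarray:
    """10·log10 of power with a −100 dB floor."""
    return 10.0 * np.log10(np.maximum(x, LOG_FLOOR))


def mel_spectrogram(y: np.ndarray) -> np.ndarray:
    """Log-power 128-band Mel spectrogram up to 11,025 Hz, hop 512."""
    S = stft_magnitude(y) ** 2
    return _log_power(mel_filterbank() @ S)


def onset_strength(y: np.ndarray) -> np.ndarray:
    """Spectral-flux onset envelope: mean over Mel bands of the half-wave
    rectified first difference of the log-power Mel spectrogram."""
    logmel = mel_spectrogram(y)
    flux = np.maximum(0.0, np.diff(logmel, axis=1))
    env = flux.mean(axis=0)
    return np.concatenate([[0.0], env])  # keep one value per frame


# ---------------------------------------------------------------------------
# The four extractors
# ---------------------------------------------------------------------------

def tempo_features(y: np.ndarray) -> FeatureMatrix:
    """Short-time onset autocorrelation (tempogram), 384 × T.

    Each column is the autocorrelation over lags 0..383 of a centered,
    Hann-windowed, 384-frame excerpt of the onset envelope (zero-padded at
    the edges), normalized by its peak amplitude.  All-zero columns (e.g.
    digital silence) are left as zeros.
    """
    env = onset_strength(y)
    frames = _frame_signal(env, TEMPO_WINDOW, 1)  # one column per envelope frame
    window = scipy.signal.get_window("hann", TEMPO_WINDOW, fftbins=True)
    windowed = frames * window
    # linear (non-circular) autocorrelation via zero-padded FFT
    n_pad = 2 * TEMPO_WINDOW
    spec = np.fft.rfft(windowed, n=n_pad, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, n=n_pad, axis=1)[:, :TEMPO_WINDOW]
    peaks = np.max(np.abs(ac), axis=1, keepdims=True)
    nz = peaks[:, 0] > 0
    ac[nz] /= peaks[nz]
    return FeatureMatrix("tempo", ac.T, SAMPLE_RATE / HOP_LENGTH)


def _scale_transform_grid(n_points: int = 128) -> np.ndarray:
    """Geometric lag grid from t0 = 0.5 to 384 frames, power-of-two length."""
    return np.geomspace(SCALE_T0, TEMPO_WINDOW - 1, n_points)


def rhythm_features(x_tau: FeatureMatrix) -> FeatureMatrix:
    """Scale-transform rhythm descriptor, 33 × T.

    Each tempo column is linearly interpolated onto a 128-point geometric
    lag grid spanning [0.5, 384) frames, weighted by √lag (the Mellin kernel
    t^{−jc−1/2} contributes e^{ξ/2} on the log-lag axis ξ), Fourier-
    transformed, and the magnitudes of the ⌊64/2⌋+1 = 33 lowest non-negative
    scale bins kept; log-power is applied last.  Multiplicative tempo changes
    become shifts on the log-lag axis, which the magnitude discards.
    """
    if x_tau.values.shape[0] != TEMPO_WINDOW:
        raise ValueError(
            f"rhythm features require {TEMPO_WINDOW}-row tempo input, "
            f"got {x_tau.values.shape[0]}"
        )
    grid = _scale_transform_grid()
    lags = np.arange(TEMPO_WINDOW, dtype=np.float64)
    cols = x_tau.values
    resampled = np.empty((grid.size, cols.shape[1]))
    for j in range(cols.shape[1]):
        resampled[:, j] = np.interp(grid, lags, cols[:, j])
    resampled *= np.sqrt(grid)[:, None]
    spec = np.fft.rfft(resampled, axis=0)
    mag = np.abs(spec[: SCALE_BINS // 2 + 1])
    return FeatureMatrix("rhythm", _log_power(mag**2), x_tau.frame_rate)


def _cq_chroma_map(n_fft: int = N_FFT, sr: int = SAMPLE_RATE) -> np.ndarray:
    """12 × (1 + n_fft/2) map folding FFT bins into pitch classes.

    FFT bins are assigned to the nearest of 36-per-octave log-frequency bins
    spanning C1–C8 and the bins of each semitone are folded into its pitch
    class (C = 0).
    """
    f_c1 = 32.70319566257483  # C1
    n_cq = 36 * 7             # C1..C8, 36 bins per octave
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    out = np.zeros((12, fft_freqs.size))
    with np.errstate(divide="ignore"):
        k = 36.0 * np.log2(fft_freqs / f_c1)
    for b, kb in enumerate(k):
        kb_round = int(round(kb)) if np.isfinite(kb) else -1
        if 0 <= kb_round < n_cq:
            pc = (kb_round // 3) % 12
            out[pc, b] = 1.0
    return out


def chroma_features(y: np.ndarray) -> FeatureMatrix:
    """Pitch-class (chroma) energy, 12 × T, per-frame peak-normalized."""
    S = stft_magnitude(y, n_fft=4096, hop=HOP_LENGTH)
    chroma = _cq_chroma_map(n_fft=4096) @ S**2
    peaks = chroma.max(axis=0, keepdims=True)
    nz = peaks[0] > 0
    chroma[:, nz] /= peaks[:, nz]
    return FeatureMatrix("chroma", chroma, SAMPLE_RATE / HOP_LENGTH)


def mfcc_features(y: np.ndarray) -> FeatureMatrix:
    """First 20 Mel-frequency cepstral coefficients, 20 × T."""
    logmel = mel_spectrogram(y)
    coeffs = scipy.fft.dct(logmel, type=2, axis=0, norm="ortho")[:20]
    return FeatureMatrix("mfcc", coeffs, SAMPLE_RATE / HOP_LENGTH)


def extract_all(y: np.ndarray) -> dict[str, FeatureMatrix]:
    """Run all four extractors on one signal."""
    tau = tempo_features(y)
    return {
        "tempo": tau,
        "rhythm": rhythm_features(tau),
        "chroma": chroma_features(y),
        "mfcc": mfcc_features(y),
    }


# ---------------------------------------------------------------------------
# Down-sampling and time-delay embedding
# ---------------------------------------------------------------------------

def _interp_to(values: np.ndarray, src_times: np.ndarray, dst_times: np.ndarray) -> np.ndarray:
    out = np.empty((values.shape[0], dst_times.size))
    for i in range(values.shape[0]):
        out[i] = np.interp(dst_times, src_times, values[i])
    return out


def time_delay_embed(values: np.ndarray, history: int = 2) -> np.ndarray:
    """Stack each frame with its ``history`` predecessors (current frame
    first); leading frames are padded by repeating the first frame."""
    parts = [values]
    for h in range(1, history + 1):
        shifted = np.concatenate([np.repeat(values[:, :1], h, axis=1), values[:, :-h]], axis=1)
        parts.append(shifted)
    return np.concatenate(parts, axis=0)


def prepare_features(
    features: dict[str, FeatureMatrix],
    duration: float,
    target_rate: float = 4.0,
) -> dict[str, FeatureMatrix]:
    """Resample all features to a shared 4 Hz grid and embed local context.

    Every matrix is linearly interpolated onto ``ceil(duration *
    target_rate)`` frames.  Chroma and MFCC — whose windows are short — are
    then time-delay embedded with the two previous frames (12→36 and 20→60
    rows) for local stability; the long-window tempo and rhythm features are
    not embedded.
    """
    n_out = math.ceil(duration * target_rate)
    dst = np.arange(n_out) / target_rate
    out: dict[str, FeatureMatrix] = {}
    for kind, fm in features.items():
        src = np.arange(fm.n_frames) / fm.frame_rate
        vals = _interp_to(fm.values, src, dst)
        if kind in ("chroma", "mfcc"):
            vals = time_delay_embed(vals, history=2)
        out[kind] = FeatureMatrix(kind, vals, target_rate)
    return out
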