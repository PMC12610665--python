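"""MFCC feature extraction for phonocardiograms.

The feature map fed to the classifier is a matrix of static mel-frequency
cepstral coefficients: rows are coefficient dimensions (the first one, DCT
coefficient 0, serves as the frame energy term), columns are analysis frames.
With the default configuration — 0.2 s Hamming frames at 50% overlap, a
2048-point FFT, 32 triangular mel filters over [0, fs/2], log compression and
an orthonormal type-II DCT — a 1.4 s recording yields a 17x13 map at either
2000 Hz or 8000 Hz sampling.

The frame count follows

    frames = floor((fs * sec - winlength) / winstep) + 1

so a window of 0.2 s stepping 0.1 s over 1.4 s of audio gives 13 frames
regardless of the sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import dct, rfft
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AudioRecording, standardize_length

__all__ = [
    "MfccConfig",
    "FeatureMap",
    "frame_count",
    "pre_emphasize",
    "mel_filterbank",
    "extract_mfcc",
    "compute_deltas",
    "MFCCTransformer",
]

LOG_FLOOR = 1e-10  # floor on filterbank energies before the log


@dataclass
class MfccConfig:
    """Feature-extraction parameters.

    win_sec : frame length in seconds (0.2 -> 1600 samples at 8 kHz,
        400 at 2 kHz)
    overlap : fractional frame overlap (0.5 -> step of half a window)
    n_fft : FFT length in points; windows shorter than this are zero-padded
    n_mels : number of triangular mel filters over [0, fs/2]
    n_static : static coefficients kept, including the energy coefficient
        (DCT coefficient 0)
    include_deltas : append delta and delta-delta rows (dims becomes
        3 * n_static)
    pre_emphasis : high-pass pre-emphasis coefficient in [0, 1)
    delta_width : half-width of the regression window for deltas
    """

    win_sec: float = 0.2
    overlap: float = 0.5
    n_fft: int = 2048
    n_mels: int = 32
    n_static: int = 17
    include_deltas: bool = False
    pre_emphasis: float = 0.97
    delta_width: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if not 0 <= self.pre_emphasis < 1:
            raise ValueError("pre_emphasis must be in [0, 1)")
        if self.n_static > self.n_mels:
            raise ValueError("n_static cannot exceed n_mels")

    def winlength(self, fs: int) -> int:
        return round(self.win_sec * fs)

    def winstep(self, fs: int) -> int:
        return round(self.win_sec * (1.0 - self.overlap) * fs)


@dataclass
class FeatureMap:
    """Coefficient matrix: rows = feature dimensions, columns = frames."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("FeatureMap is a 2-D matrix")

    @property
    def dims(self) -> int:
        return self.values.shape[0]

    @property
    def frames(self) -> int:
        return self.values.shape[1]


def frame_count(fs: float, sec: float, winlength: int, winstep: int) -> int:
    """Number of analysis frames for a signal of ``sec`` seconds at ``fs`` Hz.

    Raises if the signal is shorter than one window (zero-pad first).
    """
    if winstep <= 0:
        raise ValueError("winstep must be positive")
    n = fs * sec
    if n < winlength:
        raise ValueError("signal shorter than one analysis window")
    return int((n - winlength) // winstep) + 1


def pre_emphasize(samples: np.ndarray, alpha: float) -> np.ndarray:
    """First-difference high-pass: y[0] = x[0], y[n] = x[n] - alpha * x[n-1]."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    x = np.asarray(samples, dtype=np.float64)
    y = x.copy()
    y[1:] -= alpha * x[:-1]
    return y


def mel_filterbank(n_mels: int, n_fft: int, fs: int) -> np.ndarray:
    """Triangular unit-peak mel filterbank, shape (n_mels, n_fft // 2 + 1).

    Filter centers are equally spaced on the mel scale
    m = 2595 * log10(1 + f / 700) between 0 Hz and fs / 2.
    """

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(fs / 2.0), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.arange(n_fft // 2 + 1) * fs / n_fft
    fb = np.zeros((n_mels, freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (freqs - lo) / (ctr - lo)
        down = (hi - freqs) / (hi - ctr)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _frame_signal(x: np.ndarray, winlength: int, winstep: int) -> np.ndarray:
    n_frames = (x.size - winlength) // winstep + 1
    idx = np.arange(winlength)[None, :] + winstep * np.arange(n_frames)[:, None]
    return x[idx]


def extract_mfcc(rec: AudioRecording, cfg: MfccConfig | None = None) -> FeatureMap:
    """Compute the MFCC feature map of a (length-standardized) recording.

    Pipeline per frame: pre-emphasis, Hamming window, ``n_fft``-point power
    spectrum, 32 triangular mel-band energies, natural log with a floor at
    1e-10 (so silent frames stay finite), orthonormal type-II DCT, keep the
    first ``n_static`` coefficients.
    """
    cfg = cfg or MfccConfig()
    fs = rec.fs
    winlength, winstep = cfg.winlength(fs), cfg.winstep(fs)
    if cfg.n_fft < winlength:
        raise ValueError(f"n_fft ({cfg.n_fft}) must be >= window length ({winlength})")
    if rec.samples.size < winlength:
        raise ValueError("recording shorter than one window; standardize_length first")
    x = pre_emphasize(rec.samples, cfg.pre_emphasis)
    frames = _frame_signal(x, winlength, winstep)
    frames = frames * np.hamming(winlength)
    spectrum = rfft(frames, n=cfg.n_fft, axis=1)
    power = np.abs(spectrum) ** 2
    fb = mel_filterbank(cfg.n_mels, cfg.n_fft, fs)
    energies = power @ fb.T                       # (n_frames, n_mels)
    logged = np.log(np.maximum(energies, LOG_FLOOR))
    ceps = dct(logged, type=2, norm="ortho", axis=1)[:, : cfg.n_static]
    fm = FeatureMap(ceps.T)                       # (n_static, n_frames)
    if cfg.include_deltas:
        fm = compute_deltas(fm, half_width=cfg.delta_width)
    return fm


def compute_deltas(fm: FeatureMap, half_width: int = 2) -> FeatureMap:
    """Stack static, delta and delta-delta rows (dims -> 3 * dims).

    Deltas use the standard symmetric regression window
    d[t] = sum_n n * (c[t+n] - c[t-n]) / (2 * sum_n n^2) with edge frames
    replicated.
    """
    if fm.frames < 3:
        raise ValueError("need at least 3 frames for delta features")
    if half_width < 1:
        raise ValueError("half_width must be >= 1")

    def delta(mat: np.ndarray) -> np.ndarray:
        pad = np.pad(mat, ((0, 0), (half_width, half_width)), mode="edge")
        denom = 2.0 * sum(n * n for n in range(1, half_width + 1))
        out = np.zeros_like(mat)
        for n in range(1, half_width + 1):
            out += n * (
                pad[:, half_width + n : half_width + n + mat.shape[1]]
                - pad[:, half_width - n : half_width - n + mat.shape[1]]
            )
        return out / denom

    d1 = delta(fm.values)
    d2 = delta(FeatureMap(d1).values)
    return FeatureMap(np.vstack([fm.values, d1, d2]))


class MFCCTransformer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: recordings -> (n, dims, frames) array.

    Each input recording is standardized to ``target_sec`` seconds, then
    converted to an MFCC feature map with the configured parameters.  Fits
    nothing; ``fit`` only validates parameters, so the transformer composes
    with sklearn pipelines.
    """

    def __init__(
        self,
        target_sec: float = 1.4,
        win_sec: float = 0.2,
        overlap: float = 0.5,
        n_fft: int = 2048,
        n_mels: int = 32,
        n_static: int = 17,
        include_deltas: bool = False,
        pre_emphasis: float = 0.97,
        delta_width: int = 2,
    ):
        self.target_sec = target_sec
        self.win_sec = win_sec
        self.overlap = overlap
        self.n_fft = n_fft
        self.n_mels = n_mels
        self.n_static = n_static
        self.include_deltas = include_deltas
        self.pre_emphasis = pre_emphasis
        self.delta_width = delta_width

    def _config(self) -> MfccConfig:
        return MfccConfig(
            win_sec=self.win_sec,
            overlap=self.overlap,
            n_fft=self.n_fft,
            n_mels=self.n_mels,
            n_static=self.n_static,
            include_deltas=self.include_deltas,
            pre_emphasis=self.pre_emphasis,
            delta_width=self.delta_width,
        )

    def fit(self, X, y=None):
        self._config()  # parameter validation
        self.n_features_in_ = None
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        maps = []
        for rec in X:
            if not isinstance(rec, AudioRecording):
                raise TypeError("MFCCTransformer expects AudioRecording inputs")
            rec = standardize_length(rec, self.target_sec)
            maps.append(extract_mfcc(rec, cfg).values)
        return np.stack(maps)
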