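"""Synthetic phonocardiogram generator.

Produces labeled recordings with the structural properties the recognition
pipeline relies on — quasi-periodic S1/S2 transients at a resting heart rate,
class-conditional murmurs confined to the 100-700 Hz band, and band-structured
noise (sub-20 Hz drift, above-700 Hz hiss) with a controllable band energy
ratio — so every stage of the workflow is testable without clinical data.

This is not a physiological simulator: bursts are Gaussian-windowed tones and
murmurs are band-limited noise under class-distinct envelopes.  Only the
statistics the pipeline consumes (periodicity, band occupancy, class
separability, a known in-band/out-of-band energy ledger) are emulated.

Class templates (timing follows standard auscultation descriptions):

========  =========================================  ==============
class     murmur                                     carrier band
========  =========================================  ==============
AS        mid-systolic crescendo-decrescendo         200-450 Hz
MR        holosystolic, flat envelope                100-250 Hz
MS        diastolic decaying rumble                  100-220 Hz
MVP       mid-systolic click + late-systolic ramp    300-600 / 150-350 Hz
N         none                                       --
========  =========================================  ==============
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq

from .io import AudioRecording, DatasetManifest, write_wav

__all__ = [
    "FIVE_CLASSES",
    "BINARY_CLASSES",
    "SynthConfig",
    "SynthRecording",
    "synth_recording",
    "synth_recordings",
    "inject_noise",
    "synth_dataset",
]

FIVE_CLASSES = ("AS", "MR", "MS", "MVP", "N")
BINARY_CLASSES = ("normal", "abnormal")

_MURMUR_BANDS = {
    "AS": (200.0, 450.0),
    "MR": (100.0, 250.0),
    "MS": (100.0, 220.0),
    "MVP": (150.0, 350.0),
}
_CLICK_BAND = (300.0, 600.0)

# in-band edges shared with the quality module (kept literal here so the
# generator stands alone)
_BAND_LO, _BAND_HI = 20.0, 700.0
_DRIFT_BAND = (1.0, 18.0)
_HISS_BAND = (720.0, 950.0)


@dataclass
class SynthConfig:
    """Generative parameters for one synthetic recording.

    ``class_spec`` is one of the five valve classes or ``normal`` /
    ``abnormal`` (the latter draws one of the four pathological templates).
    ``target_ber`` optionally injects drift + hiss so the in-band to
    out-of-band energy ratio of the final waveform equals the target.
    """

    fs: int = 8000
    class_spec: str = "N"
    duration_range: tuple[float, float] = (1.2, 4.0)
    heart_rate_bpm: tuple[float, float] = (60.0, 100.0)
    s1_band: tuple[float, float] = (30.0, 100.0)
    s2_band: tuple[float, float] = (50.0, 150.0)
    murmur_amp: float = 0.35
    target_ber: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        valid = set(FIVE_CLASSES) | set(BINARY_CLASSES)
        if self.class_spec not in valid:
            raise ValueError(f"class_spec must be one of {sorted(valid)}")
        lo, hi = self.heart_rate_bpm
        if not 20.0 <= lo < hi <= 250.0:
            raise ValueError("heart_rate_bpm outside plausible clinical bounds")
        for band in (self.s1_band, self.s2_band):
            if not 0.0 < band[0] < band[1] < self.fs / 2:
                raise ValueError(f"band {band} outside (0, fs/2)")
        d0, d1 = self.duration_range
        if not 0.0 < d0 <= d1:
            raise ValueError("invalid duration_range")
        if self.target_ber is not None and self.target_ber <= 0:
            raise ValueError("target_ber must be positive")


@dataclass
class SynthRecording:
    """A generated recording plus its generation-time ground truth.

    ``ground_truth`` holds S1/S2 event times, murmur windows, and a spectral
    energy ledger of the final waveform: ``in_band`` (20-700 Hz), ``out_band``
    (everything else except DC), ``dc`` and ``total``.  The three parts sum to
    the total signal energy (Parseval).
    """

    recording: AudioRecording
    ground_truth: dict = field(default_factory=dict)


def _bandlimited_noise(n: int, fs: int, band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS white noise confined to ``band`` by spectral masking."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, 1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} empty at fs={fs}")
    x = irfft(np.where(mask, spec, 0.0), n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / max(rms, 1e-30)


def _burst(t: np.ndarray, center: float, dur: float, freq: float, phase: float,
           amp: float) -> np.ndarray:
    sigma = dur / 6.0
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return amp * env * np.sin(2.0 * np.pi * freq * (t - center) + phase)


def _spectral_ledger(x: np.ndarray, fs: int) -> dict:
    """Parseval band split of the signal energy (time-domain sum of squares)."""
    n = x.size
    spec = np.abs(rfft(x)) ** 2
    # rfft Parseval: sum x^2 = (spec[0] + 2*sum(spec[1:-1]) + w*spec[-1]) / n
    w = np.full(spec.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    contrib = w * spec / n
    f = rfftfreq(n, 1.0 / fs)
    in_mask = (f >= _BAND_LO) & (f <= _BAND_HI)
    out_mask = ((f > 0) & (f < _BAND_LO)) | (f > _BAND_HI)
    return {
        "in_band": float(contrib[in_mask].sum()),
        "out_band": float(contrib[out_mask].sum()),
        "dc": float(contrib[0]),
        "total": float(contrib.sum()),
    }


def _envelope(kind: str, m: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, m)
    if kind == "diamond":
        env = 1.0 - np.abs(2.0 * tau - 1.0)
    elif kind == "flat":
        env = np.minimum(1.0, np.minimum(tau, 1.0 - tau) * 8.0)  # soft edges
    elif kind == "decay":
        env = np.exp(-3.0 * tau)
    elif kind == "ramp":
        env = tau
    else:
        raise ValueError(kind)
    return env


def synth_recording(cfg: SynthConfig) -> SynthRecording:
    """Generate one synthetic PCG recording, deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    duration = rng.uniform(*cfg.duration_range)
    n = round(duration * fs)
    t = np.arange(n) / fs
    hr = rng.uniform(*cfg.heart_rate_bpm)
    period = 60.0 / hr

    label = cfg.class_spec
    template = label
    if label == "normal":
        template = "N"
    elif label == "abnormal":
        template = FIVE_CLASSES[rng.integers(4)]  # one of AS/MR/MS/MVP

    x = np.zeros(n)
    s1_times, s2_times = [], []
    cycles = []
    start = 0.0
    while start < duration:
        s1_c = start + 0.05
        s2_c = start + 0.35 * period
        if s1_c < duration:
            f1 = rng.uniform(*cfg.s1_band)
            x += _burst(t, s1_c, 0.12, f1, rng.uniform(0, 2 * np.pi),
                        amp=rng.uniform(0.9, 1.1))
            s1_times.append(s1_c)
        if s2_c < duration:
            f2 = rng.uniform(*cfg.s2_band)
            x += _burst(t, s2_c, 0.09, f2, rng.uniform(0, 2 * np.pi),
                        amp=0.6 * rng.uniform(0.9, 1.1))
            s2_times.append(s2_c)
        cycles.append(start)
        start += period

    # murmurs last, scaled linearly by murmur_amp: with murmur_amp == 0 the
    # waveform is sample-identical to the normal class under the same seed
    murmur_windows = []
    for start in cycles:
        sys_w = (start + 0.12, start + 0.35 * period - 0.05)
        dia_w = (start + 0.35 * period + 0.07, start + period - 0.05)
        specs = []  # (window, envelope kind, band, relative amp)
        if template == "AS":
            specs.append((sys_w, "diamond", _MURMUR_BANDS["AS"], 1.0))
        elif template == "MR":
            specs.append((sys_w, "flat", _MURMUR_BANDS["MR"], 1.0))
        elif template == "MS":
            specs.append((dia_w, "decay", _MURMUR_BANDS["MS"], 1.0))
        elif template == "MVP":
            mid = 0.5 * (sys_w[0] + sys_w[1])
            specs.append(((mid - 0.015, mid + 0.015), "diamond", _CLICK_BAND, 1.6))
            specs.append(((mid, sys_w[1]), "ramp", _MURMUR_BANDS["MVP"], 1.0))
        for (w0, w1), env_kind, band, rel in specs:
            i0, i1 = max(0, round(w0 * fs)), min(n, round(w1 * fs))
            m = i1 - i0
            # windows clipped at the recording edge can be too short for any
            # FFT bin to fall inside the murmur band — skip those
            if m < 8 or not np.any((rfftfreq(m, 1.0 / fs) >= band[0])
                                   & (rfftfreq(m, 1.0 / fs) <= band[1])):
                continue
            noise = _bandlimited_noise(m, fs, band, rng)
            x[i0:i1] += cfg.murmur_amp * rel * _envelope(env_kind, m) * noise
            if cfg.murmur_amp > 0:
                murmur_windows.append((i0 / fs, i1 / fs))

    gt = {
        "label": label,
        "template": template,
        "fs": fs,
        "duration": duration,
        "heart_rate_bpm": hr,
        "s1_times": s1_times,
        "s2_times": s2_times,
        "murmur_windows": murmur_windows,
        "energy_ledger": _spectral_ledger(x, fs),
    }
    sr = SynthRecording(
        recording=AudioRecording(samples=x, fs=fs, label=label), ground_truth=gt
    )
    if cfg.target_ber is not None:
        sr = inject_noise(sr, cfg.target_ber, seed=int(rng.integers(2**31)))
    return sr


def inject_noise(sr: SynthRecording, target_ber: float, seed: int = 0) -> SynthRecording:
    """Add low-frequency drift and high-frequency hiss so the ledger's
    in-band / out-of-band energy ratio equals ``target_ber``.

    Noise can only lower the ratio, so the target must lie below the clean
    signal's current ratio.  When the sampling rate leaves no room above
    700 Hz, drift alone is injected and the result is flagged in the ground
    truth (``noise_fallback``).
    """
    if target_ber <= 0:
        raise ValueError("target_ber must be positive")
    rec = sr.recording
    fs, n = rec.fs, rec.samples.size
    rng = np.random.default_rng(seed)

    ledger = _spectral_ledger(rec.samples, fs)
    e_in0, e_out0 = ledger["in_band"], ledger["out_band"]
    if e_in0 - target_ber * e_out0 <= 0:
        raise ValueError(
            f"target_ber {target_ber} is not below the clean ratio "
            f"{e_in0 / max(e_out0, 1e-30):.3g}; noise injection can only lower it"
        )

    drift = _bandlimited_noise(n, fs, _DRIFT_BAND, rng)
    fallback = _HISS_BAND[0] >= fs / 2
    if fallback:
        z = drift
    else:
        hi = (_HISS_BAND[0], min(_HISS_BAND[1], 0.98 * fs / 2))
        z = drift + _bandlimited_noise(n, fs, hi, rng)

    # per-band energies of y = x + a z are quadratic in a:
    #   E_band(a) = Ex + a*Cx + a^2*Ez   with Cx from the X-Z cross spectrum;
    # solve E_in(a) - target * E_out(a) = 0 exactly so the ledger ratio hits
    # the target to numerical precision
    X, Z = rfft(rec.samples), rfft(z)
    w = np.full(X.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    f = rfftfreq(n, 1.0 / fs)
    in_mask = (f >= _BAND_LO) & (f <= _BAND_HI)
    out_mask = ((f > 0) & (f < _BAND_LO)) | (f > _BAND_HI)
    cross = 2.0 * w * (X.conj() * Z).real / n
    zsq = w * np.abs(Z) ** 2 / n
    A = zsq[in_mask].sum() - target_ber * zsq[out_mask].sum()
    B = cross[in_mask].sum() - target_ber * cross[out_mask].sum()
    C = e_in0 - target_ber * e_out0
    disc = B * B - 4 * A * C
    if disc < 0:
        raise ValueError("target_ber unreachable with the available noise bands")
    roots = [r for r in np.roots([A, B, C]) if np.isreal(r) and r.real > 0]
    if not roots:
        raise ValueError("target_ber unreachable with the available noise bands")
    a = float(min(r.real for r in roots))
    y = rec.samples + a * z

    gt = dict(sr.ground_truth)
    gt["energy_ledger"] = _spectral_ledger(y, fs)
    gt["target_ber"] = target_ber
    gt["noise_fallback"] = bool(fallback)
    return SynthRecording(recording=replace(rec, samples=y), ground_truth=gt)


def synth_recordings(
    n_per_class: int,
    template: SynthConfig | None = None,
    seed: int = 0,
    binary: bool = False,
    imbalance: float = 4.0,
) -> list[SynthRecording]:
    """Generate a labeled collection in memory.

    Five balanced classes by default; ``binary`` generates ``n_per_class``
    abnormal and ``round(imbalance * n_per_class)`` normal recordings.
    Per-recording seeds derive from ``seed``, so generation is reproducible
    file-by-file.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    template = template or SynthConfig()
    master = np.random.default_rng(seed)
    plan: list[str] = []
    if binary:
        plan += ["abnormal"] * n_per_class
        plan += ["normal"] * round(imbalance * n_per_class)
    else:
        for lab in FIVE_CLASSES:
            plan += [lab] * n_per_class
    out = []
    for i, lab in enumerate(plan):
        cfg = replace(template, class_spec=lab, seed=int(master.integers(2**31)))
        sr = synth_recording(cfg)
        sr.recording.record_id = f"{lab}_{i:04d}"
        sr.ground_truth["record_id"] = sr.recording.record_id
        out.append(sr)
    return out


def synth_dataset(
    out_dir: str | os.PathLike,
    n_per_class: int = 200,
    template: SynthConfig | None = None,
    seed: int = 0,
    binary: bool = False,
    imbalance: float = 4.0,
) -> DatasetManifest:
    """Write a synthetic dataset to disk: WAV files (16-bit PCM), a
    ``manifest.csv`` in the ``record_id,path,label`` dialect, and a
    ``ledger.json`` with per-record ground truth."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    recs = synth_recordings(n_per_class, template=template, seed=seed,
                            binary=binary, imbalance=imbalance)
    entries = []
    ledger = {}
    for sr in recs:
        rec = sr.recording
        peak = np.abs(rec.samples).max()
        scaled = replace(rec, samples=rec.samples / peak * 0.9 if peak > 0 else rec.samples)
        path = os.path.join(out_dir, f"{rec.record_id}.wav")
        write_wav(path, scaled)
        entries.append((rec.record_id, path, rec.label))
        ledger[rec.record_id] = sr.ground_truth
    label_set = BINARY_CLASSES if binary else FIVE_CLASSES
    manifest = DatasetManifest(entries=entries, label_set=tuple(label_set))
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"))
    with open(os.path.join(out_dir, "ledger.json"), "w") as fh:
        json.dump(ledger, fh, indent=1)
    return manifest
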