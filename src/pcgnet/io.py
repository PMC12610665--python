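"""Audio I/O, length standardization and file-level dataset splitting.

Phonocardiogram (PCG) corpora ship as directories of mono PCM WAV files with a
per-file class label.  This module reads and writes those files, resamples
them, standardizes every recording to a fixed analysis length, and performs
dataset splitting *strictly at the whole-file level* so that no segment of a
recording ever appears in both the train and the test partition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioRecording",
    "DatasetManifest",
    "SplitPlan",
    "read_wav",
    "write_wav",
    "resample",
    "standardize_length",
    "split_dataset",
]

# peak-normalization headroom when quantizing to 16-bit PCM
_INT16_FULL_SCALE = 32768.0


@dataclass
class AudioRecording:
    """A labeled mono waveform.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude samples (dimensionless).
    fs : int
        Sampling rate in Hz.
    label : str, optional
        Class name drawn from the dataset's label set.
    record_id : str, optional
        Unique identifier (file stem by convention).
    """

    samples: np.ndarray
    fs: int
    label: str | None = None
    record_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioRecording holds mono audio (1-D samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.fs


@dataclass
class DatasetManifest:
    """Index of a labeled audio dataset: (record_id, path, label) rows."""

    entries: list[tuple[str, str, str]]
    label_set: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("record_id values must be unique")
        bad = {e[2] for e in self.entries} - set(self.label_set)
        if bad:
            raise ValueError(f"labels outside the declared label set: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def labels_by_id(self) -> dict[str, str]:
        return {rid: lab for rid, _, lab in self.entries}

    @classmethod
    def from_csv(cls, path: str | os.PathLike, label_set=None) -> "DatasetManifest":
        """Load a manifest CSV with header ``record_id,path,label``."""
        df = pd.read_csv(path, dtype=str)
        required = {"record_id", "path", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        entries = list(df[["record_id", "path", "label"]].itertuples(index=False, name=None))
        if label_set is None:
            label_set = tuple(sorted(df["label"].unique()))
        return cls(entries=entries, label_set=tuple(label_set))

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(self.entries, columns=["record_id", "path", "label"]).to_csv(
            path, index=False
        )


@dataclass
class SplitPlan:
    """How to partition a manifest into train/test id sets.

    ``scheme`` is ``"holdout"`` (single ``train_fraction`` split, stratified by
    class) or ``"kfold"`` (``k`` rotating disjoint test sets covering the
    manifest).  ``sampling`` selects the k-fold test-set design: ``"balanced"``
    forces equal per-class counts in every fold, ``"random"`` draws folds
    without class constraints.
    """

    scheme: str = "kfold"
    train_fraction: float = 0.9
    k: int = 10
    sampling: str = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("holdout", "kfold"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "holdout" and not 0 < self.train_fraction < 1:
            raise ValueError("holdout needs 0 < train_fraction < 1")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("kfold needs k >= 2")
        if self.sampling not in ("balanced", "random"):
            raise ValueError(f"unknown sampling {self.sampling!r}")


def read_wav(path: str | os.PathLike) -> AudioRecording:
    """Read a PCM or float WAV file as a mono float recording.

    Integer PCM is rescaled to [-1, 1); multi-channel input is reduced to mono
    by averaging channels.
    """
    try:
        fs, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"not a readable WAV file: {path}") from exc
    data = np.asarray(data)
    if data.dtype == np.int16:
        x = data / _INT16_FULL_SCALE
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32 / float64 WAV
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    rid = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return AudioRecording(samples=x, fs=int(fs), record_id=rid)


def write_wav(path: str | os.PathLike, rec: AudioRecording, dtype: str = "int16") -> None:
    """Write a recording as 16-bit PCM (default) or float32 WAV."""
    if dtype == "int16":
        x = np.clip(rec.samples, -1.0, 1.0 - 1.0 / _INT16_FULL_SCALE)
        wavfile.write(path, rec.fs, (x * _INT16_FULL_SCALE).astype(np.int16))
    elif dtype == "float32":
        wavfile.write(path, rec.fs, rec.samples.astype(np.float32))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")


def resample(rec: AudioRecording, target_fs: int) -> AudioRecording:
    """Polyphase-resample a recording to ``target_fs`` Hz."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs, rec.fs)
    y = resample_poly(rec.samples, frac.numerator, frac.denominator)
    return replace(rec, samples=y, fs=target_fs)


def standardize_length(rec: AudioRecording, target_sec: float = 1.4) -> AudioRecording:
    """Truncate or zero-pad a recording to exactly ``round(fs * target_sec)``
    samples.

    Truncation keeps the initial portion of the signal; padding appends zeros
    at the end.  Idempotent.
    """
    if target_sec <= 0:
        raise ValueError("target_sec must be positive")
    n = round(rec.fs * target_sec)
    x = rec.samples
    if x.size >= n:
        y = x[:n].copy()
    else:
        y = np.concatenate([x, np.zeros(n - x.size)])
    return replace(rec, samples=y)


def _split_holdout(manifest: DatasetManifest, plan: SplitPlan, rng: np.random.Generator):
    by_class: dict[str, list[str]] = {lab: [] for lab in manifest.label_set}
    for rid, _, lab in manifest.entries:
        by_class[lab].append(rid)
    train: list[str] = []
    test: list[str] = []
    for lab in manifest.label_set:
        ids = np.array(by_class[lab])
        rng.shuffle(ids)
        n_train = round(plan.train_fraction * ids.size)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return [(train, test)]


def _split_kfold(manifest: DatasetManifest, plan: SplitPlan, rng: np.random.Generator):
    all_ids = list(manifest.ids)
    folds_test: list[list[str]]
    if plan.sampling == "balanced":
        by_class: dict[str, list[str]] = {lab: [] for lab in manifest.label_set}
        for rid, _, lab in manifest.entries:
            by_class[lab].append(rid)
        per_fold = {}
        for lab, ids in by_class.items():
            if len(ids) < plan.k or len(ids) % plan.k != 0:
                raise ValueError(
                    f"balanced {plan.k}-fold split needs class sizes divisible by k; "
                    f"class {lab!r} has {len(ids)} members"
                )
            per_fold[lab] = len(ids) // plan.k
        folds_test = [[] for _ in range(plan.k)]
        for lab in manifest.label_set:
            ids = np.array(by_class[lab])
            rng.shuffle(ids)
            m = per_fold[lab]
            for i in range(plan.k):
                folds_test[i].extend(ids[i * m : (i + 1) * m])
    else:
        ids = np.array(all_ids)
        rng.shuffle(ids)
        folds_test = [list(part) for part in np.array_split(ids, plan.k)]
    pairs = []
    for test in folds_test:
        test_set = set(test)
        train = [rid for rid in all_ids if rid not in test_set]
        pairs.append((train, list(test)))
    return pairs


def split_dataset(
    manifest: DatasetManifest, plan: SplitPlan
) -> list[tuple[list[str], list[str]]]:
    """Partition a manifest into (train ids, test ids) pairs.

    Holdout returns a single pair; k-fold returns ``k`` pairs whose test sets
    are pairwise disjoint and jointly cover the manifest.  Deterministic under
    ``plan.seed``.
    """
    rng = np.random.default_rng(plan.seed)
    if plan.scheme == "holdout":
        return _split_holdout(manifest, plan, rng)
    return _split_kfold(manifest, plan, rng)
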