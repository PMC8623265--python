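"""Time-domain features, min-max normalization and spectral fatigue indicators.

Four features per channel per window — root mean square (RMS), waveform
length (WL), thresholded zero crossings (ZC) and slope-sign changes
(SSC) — giving a 16-dimensional vector on the 4-channel montage. ZC and
SSC use an absolute amplitude threshold ``eps`` (default 20 signal
units) as a guard against baseline noise: a crossing or slope reversal
only counts if the adjacent sample step clears the threshold.

The spectral side provides the classic fatigue indicators: Welch power
spectral density and its mean power frequency (MPF), the PSD-weighted
mean of the frequency axis. Under fatigue RMS rises and MPF falls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import CHANNEL_NAMES
from .preprocessing import Window

#: Default ZC/SSC amplitude threshold, in signal units (mV-scale).
DEFAULT_EPSILON = 20.0

FEATURE_NAMES = ("RMS", "WL", "ZC", "SSC")
#: Channel-major feature column order: [RMS, WL, ZC, SSC] for CH1, then CH2, ...
FEATURE_COLUMNS = [f"{ch}_{f}" for ch in CHANNEL_NAMES for f in FEATURE_NAMES]
META_COLUMNS = ["gesture", "subject", "day", "fatigue", "angle", "group", "window"]


def rms(x) -> float | np.ndarray:
    """Root mean square: sqrt of the mean squared amplitude (along the last axis)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 1:
        raise ValueError("rms needs at least one sample")
    return np.sqrt(np.mean(np.square(x), axis=-1))


def wl(x) -> float | np.ndarray:
    """Waveform length: cumulative absolute sample-to-sample variation."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("wl needs at least two samples")
    return np.sum(np.abs(np.diff(x, axis=-1)), axis=-1)


def zc(x, eps: float = DEFAULT_EPSILON) -> int | np.ndarray:
    """Thresholded zero crossings.

    Counts sample pairs whose product is negative (a sign change) and
    whose amplitude step exceeds ``eps``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("zc needs at least two samples")
    prev, cur = x[..., :-1], x[..., 1:]
    hits = (cur * prev < 0) & (np.abs(cur - prev) > eps)
    return np.sum(hits, axis=-1)


def ssc(x, eps: float = DEFAULT_EPSILON) -> int | np.ndarray:
    """Thresholded slope-sign changes.

    Counts interior samples where the local slope reverses sign and at
    least one of the two adjacent slopes exceeds ``eps`` in magnitude.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("ssc needs at least three samples")
    d = np.diff(x, axis=-1)
    a, b = d[..., :-1], d[..., 1:]
    hits = (a * b < 0) & ((np.abs(a) > eps) | (np.abs(b) > eps))
    return np.sum(hits, axis=-1)


def feature_vector(samples: np.ndarray, eps: float = DEFAULT_EPSILON) -> np.ndarray:
    """16-dim channel-major feature vector for one (channels, N) window."""
    samples = np.asarray(samples, dtype=float)
    cols = np.stack(
        [rms(samples), wl(samples), zc(samples, eps), ssc(samples, eps)], axis=1
    )  # (channels, 4)
    return cols.reshape(-1).astype(float)


def extract(windows: Sequence[Window], eps: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Feature matrix: one labeled 16-dim row per window.

    Columns: :data:`FEATURE_COLUMNS` plus gesture label and condition
    metadata. Stateless — permuting the input windows permutes rows
    identically.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("extract needs at least one window")
    n_ch = windows[0].samples.shape[0]
    if any(w.samples.shape[0] != n_ch for w in windows):
        raise ValueError("all windows must have the same channel count")
    feats = np.array([feature_vector(w.samples, eps) for w in windows])
    cols = (
        FEATURE_COLUMNS
        if n_ch == len(CHANNEL_NAMES)
        else [f"CH{c + 1}_{f}" for c in range(n_ch) for f in FEATURE_NAMES]
    )
    df = pd.DataFrame(feats, columns=cols)
    df["gesture"] = [w.gesture_id for w in windows]
    df["subject"] = [w.subject_id for w in windows]
    df["day"] = [w.condition.day for w in windows]
    df["fatigue"] = [w.condition.fatigue for w in windows]
    df["angle"] = [w.condition.angle for w in windows]
    df["group"] = [w.group for w in windows]
    df["window"] = [w.start for w in windows]
    return df


@dataclass
class MinMaxNormalizer:
    """Per-column min-max scaling fit on training rows only.

    Training columns map onto [0, 1] exactly; test rows may fall
    outside. A constant training column maps to 0 everywhere.
    """

    columns: List[str] | None = None
    mins: np.ndarray | None = None
    ranges: np.ndarray | None = None

    def fit(self, frame: pd.DataFrame, columns: Sequence[str] | None = None) -> "MinMaxNormalizer":
        self.columns = list(
            columns
            if columns is not None
            else [c for c in FEATURE_COLUMNS if c in frame.columns]
        )
        if frame.empty:
            raise ValueError("cannot fit a normalizer on an empty frame")
        values = frame[self.columns].to_numpy(dtype=float)
        self.mins = values.min(axis=0)
        rng = values.max(axis=0) - self.mins
        rng[rng == 0] = 1.0  # constant column -> maps to 0
        self.ranges = rng
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if self.mins is None:
            raise ValueError("normalizer is not fitted")
        out = frame.copy()
        out[self.columns] = (
            frame[self.columns].to_numpy(dtype=float) - self.mins
        ) / self.ranges
        return out

    def fit_transform(self, frame: pd.DataFrame, **kw) -> pd.DataFrame:
        return self.fit(frame, **kw).transform(frame)


def fit_normalizer(train: pd.DataFrame, columns: Sequence[str] | None = None) -> MinMaxNormalizer:
    return MinMaxNormalizer().fit(train, columns)


def apply_normalizer(normalizer: MinMaxNormalizer, frame: pd.DataFrame) -> pd.DataFrame:
    return normalizer.transform(frame)


@dataclass
class SpectralSummary:
    """Welch PSD with its mean power frequency and whole-signal RMS."""

    frequencies: np.ndarray
    psd: np.ndarray
    mpf: float
    rms: float


def spectral_summary(
    x: np.ndarray,
    sampling_rate: float,
    nperseg: int = 512,
) -> SpectralSummary:
    """Welch PSD (Hann taper, 50% overlap) and spectral fatigue indicators.

    MPF is the PSD-weighted mean frequency: sum(f * P) / sum(P).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("spectral_summary takes a single-channel series")
    if x.size < 2 * nperseg:
        raise ValueError(
            f"signal of {x.size} samples is too short for {nperseg}-sample PSD segments"
        )
    f, p = sps.welch(
        x, fs=sampling_rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    total = p.sum()
    mpf = float((f * p).sum() / total) if total > 0 else float("nan")
    return SpectralSummary(frequencies=f, psd=p, mpf=mpf, rms=float(rms(x)))
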