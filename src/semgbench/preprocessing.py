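"""Bandpass filtering, valid-segment trimming and sliding-window segmentation.

Offline pipeline order is fixed: filter the raw trial, trim it to its
valid interval (the ramp-up/ramp-down seconds around a gesture are
transition artifacts), then cut overlapping analysis windows. Trimming
before windowing guarantees no window spans a trim boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import signal as sps

from .core import ConditionKey, Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass. Zero-phase (forward-backward) by default,
    appropriate for offline analysis: no phase distortion of features."""

    low_cut: float = 20.0
    high_cut: float = 500.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis window: 400 ms length, 50 ms step by default."""

    length_ms: float = 400.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.length_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window length and step must be positive")
        if self.step_ms > self.length_ms:
            raise ValueError("step must not exceed window length")

    def in_samples(self, sampling_rate: float) -> Tuple[int, int]:
        length = self.length_ms * sampling_rate / 1000.0
        step = self.step_ms * sampling_rate / 1000.0
        for name, v in (("length", length), ("step", step)):
            if abs(v - round(v)) > 1e-9:
                raise ValueError(
                    f"window {name} {v} is not a whole sample count at {sampling_rate} Hz"
                )
        return int(round(length)), int(round(step))


@dataclass
class Window:
    """One analysis window: (channels, N) samples plus source metadata."""

    samples: np.ndarray
    sampling_rate: float
    gesture_id: str
    subject_id: str
    condition: ConditionKey
    group: int
    start: int  # start index within the (trimmed) recording

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]


# Valid-data intervals (seconds) within a trial, by fatigue class: the
# rested 5 s trials keep their middle three seconds, the sustained 15 s
# fatigue trials keep the late [12, 14) s interval where fatigue is
# established. Intervals are half-open, indices 0-based.
CLASS_A_VALID: Tuple[float, float] = (1.0, 4.0)
CLASS_B_VALID: Tuple[float, float] = (12.0, 14.0)


def bandpass(recording: Recording, spec: FilterSpec | None = None) -> Recording:
    """Filter each channel independently; shape and metadata preserved."""
    spec = spec or FilterSpec()
    nyq = recording.sampling_rate / 2.0
    if spec.high_cut >= nyq:
        raise ValueError(
            f"high_cut {spec.high_cut} Hz must be below the Nyquist rate {nyq} Hz"
        )
    sos = sps.butter(
        spec.order,
        [spec.low_cut / nyq, spec.high_cut / nyq],
        btype="bandpass",
        output="sos",
    )
    filt = sps.sosfiltfilt if spec.zero_phase else sps.sosfilt
    return recording.with_samples(filt(sos, recording.samples, axis=-1))


def trim_valid(
    recording: Recording,
    class_a_window: Tuple[float, float] = CLASS_A_VALID,
    class_b_window: Tuple[float, float] = CLASS_B_VALID,
) -> Recording:
    """Keep only the valid interval of a trial, by fatigue class.

    The class-b interval default reads "12-14 s" as the half-open
    [12 s, 14 s); pass ``class_b_window=(12.0, 15.0)`` for the
    three-second reading.
    """
    fatigue = recording.condition.fatigue
    t0, t1 = class_a_window if fatigue == "a" else class_b_window
    needed = t1
    if recording.duration < needed - 1e-9:
        raise ValueError(
            f"class {fatigue} trial of {recording.duration:.3f} s is too short: "
            f"valid interval [{t0}, {t1}) s requires >= {needed} s"
        )
    i0 = int(round(t0 * recording.sampling_rate))
    i1 = int(round(t1 * recording.sampling_rate))
    return recording.with_samples(recording.samples[:, i0:i1])


def segment(recording: Recording, spec: WindowSpec | None = None) -> List[Window]:
    """Cut complete overlapping windows: starts 0, S, 2S, ...; length L.

    Count = floor((T - L)/S) + 1. A recording shorter than one window
    yields an empty list (with a logged warning), not an error.
    """
    spec = spec or WindowSpec()
    length, step = spec.in_samples(recording.sampling_rate)
    total = recording.n_samples
    if total < length:
        logger.warning(
            "recording of %d samples shorter than one %d-sample window; no windows",
            total,
            length,
        )
        return []
    starts = range(0, total - length + 1, step)
    return [
        Window(
            samples=recording.samples[:, s : s + length],
            sampling_rate=recording.sampling_rate,
            gesture_id=recording.gesture_id,
            subject_id=recording.subject_id,
            condition=recording.condition,
            group=recording.group,
            start=s,
        )
        for s in starts
    ]


def preprocess(
    recording: Recording,
    filter_spec: FilterSpec | None = None,
    window_spec: WindowSpec | None = None,
    class_b_window: Tuple[float, float] = CLASS_B_VALID,
) -> List[Window]:
    """Full chain: bandpass -> trim_valid -> segment."""
    filtered = bandpass(recording, filter_spec)
    trimmed = trim_valid(filtered, class_b_window=class_b_window)
    return segment(trimmed, window_spec)
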