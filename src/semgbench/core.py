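"""Shared domain types for the sEMG gesture-decoding benchmark.

The study design enumerates recordings along three condition axes:
acquisition day (A/B/C, one day apart), muscle-fatigue class
(``a`` = rested, 5 s trials; ``b`` = fatigued, 15 s sustained trials)
and forearm angle (30/45/75 degrees). Each (day, fatigue, angle)
triple is one of 18 dataset classes; each class holds several
independently recorded *groups*, and each group contains one trial per
gesture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np

#: The 11 analyzed static gestures: hand close/open, wrist
#: flexion/extension, ulnar/radial deviation, thumb-to-finger touches
#: and five-fingertip touch.
GESTURES: Tuple[str, ...] = (
    "HC", "HO", "WF", "WE", "UD", "RD", "TI", "TM", "TR", "TL", "FL",
)
#: Relax/rest reference gesture — recorded but excluded from classification.
REST_GESTURE: str = "RE"
ALL_GESTURES: Tuple[str, ...] = GESTURES + (REST_GESTURE,)

DAYS: Tuple[str, ...] = ("A", "B", "C")
FATIGUE_CLASSES: Tuple[str, ...] = ("a", "b")
ANGLES: Tuple[int, ...] = (30, 45, 75)

#: Electrode channels over the four forearm muscles: superficial flexor
#: digitorum, flexor carpi ulnaris, extensor carpi radialis longus,
#: finger extensor.
CHANNEL_NAMES: Tuple[str, ...] = ("CH1", "CH2", "CH3", "CH4")
N_CHANNELS: int = 4


@dataclass(frozen=True, order=True)
class ConditionKey:
    """One of the 18 dataset classes: (day, fatigue class, forearm angle)."""

    day: str
    fatigue: str
    angle: int

    def __post_init__(self) -> None:
        if self.day not in DAYS:
            raise ValueError(f"unknown acquisition day {self.day!r}; expected one of {DAYS}")
        if self.fatigue not in FATIGUE_CLASSES:
            raise ValueError(
                f"unknown fatigue class {self.fatigue!r}; expected one of {FATIGUE_CLASSES}"
            )
        if self.angle not in ANGLES:
            raise ValueError(f"unknown forearm angle {self.angle!r}; expected one of {ANGLES}")

    @property
    def label(self) -> str:
        """Dataset-class name, e.g. ``"A_b_30"``."""
        return f"{self.day}_{self.fatigue}_{self.angle}"

    @classmethod
    def from_label(cls, label: str) -> "ConditionKey":
        try:
            day, fatigue, angle = label.split("_")
            return cls(day=day, fatigue=fatigue, angle=int(angle))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed condition label {label!r}; expected e.g. 'A_b_30'") from exc

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def all_condition_keys(
    days: Sequence[str] = DAYS,
    fatigue_classes: Sequence[str] = FATIGUE_CLASSES,
    angles: Sequence[int] = ANGLES,
) -> List[ConditionKey]:
    """Enumerate the dataset-class taxonomy (18 keys at full design)."""
    return [
        ConditionKey(d, f, a) for d in days for f in fatigue_classes for a in angles
    ]


@dataclass
class Recording:
    """One gesture trial: raw multi-channel signal plus condition metadata.

    ``samples`` is a ``(n_channels, n_samples)`` float array in the
    amplitude units of the acquisition chain (mV-scale by convention;
    the 20-unit zero-crossing threshold is calibrated against it).
    """

    samples: np.ndarray
    sampling_rate: float
    gesture_id: str
    subject_id: str
    condition: ConditionKey
    group: int
    channel_names: Tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with the signal replaced, metadata kept."""
        return replace(self, samples=np.asarray(samples, dtype=float))


class DatasetRegistry:
    """Map from (subject, condition key, group) to the group's recordings.

    Each entry holds one :class:`Recording` per gesture. The registry is
    the handoff surface between signal generation/loading and the
    cross-condition evaluation designs.
    """

    def __init__(self) -> None:
        self._data: Dict[Tuple[str, ConditionKey, int], Dict[str, Recording]] = {}

    def add(self, recording: Recording) -> None:
        slot = self._data.setdefault(
            (recording.subject_id, recording.condition, recording.group), {}
        )
        slot[recording.gesture_id] = recording

    def get(self, subject_id: str, key: ConditionKey, group: int) -> Dict[str, Recording]:
        return self._data[(subject_id, key, group)]

    @property
    def subjects(self) -> List[str]:
        return sorted({s for s, _, _ in self._data})

    def condition_keys(self, subject_id: str | None = None) -> List[ConditionKey]:
        keys = {
            k for s, k, _ in self._data if subject_id is None or s == subject_id
        }
        return sorted(keys)

    def groups(self, subject_id: str, key: ConditionKey) -> List[int]:
        return sorted({g for s, k, g in self._data if s == subject_id and k == key})

    def recordings(self) -> Iterator[Recording]:
        for slot in self._data.values():
            yield from slot.values()

    def __len__(self) -> int:
        return sum(len(slot) for slot in self._data.values())

    def __contains__(self, item: Tuple[str, ConditionKey, int]) -> bool:
        return item in self._data

    def validate(
        self,
        expected_keys: Sequence[ConditionKey] | None = None,
        expected_groups: Sequence[int] | None = None,
        gestures: Sequence[str] = ALL_GESTURES,
    ) -> None:
        """Check completeness: every subject has every key x group x gesture.

        Raises ``ValueError`` naming the first gap found.
        """
        if not self._data:
            raise ValueError("registry is empty")
        keys = list(expected_keys) if expected_keys is not None else self.condition_keys()
        for subject in self.subjects:
            present = set(self.condition_keys(subject))
            for key in keys:
                if key not in present:
                    raise ValueError(
                        f"subject {subject}: missing dataset class {key.label}"
                    )
                groups = (
                    list(expected_groups)
                    if expected_groups is not None
                    else self.groups(subject, key)
                )
                for group in groups:
                    if (subject, key, group) not in self._data:
                        raise ValueError(
                            f"subject {subject}: missing group {group} in {key.label}"
                        )
                    have = self._data[(subject, key, group)]
                    for gesture in gestures:
                        if gesture not in have:
                            raise ValueError(
                                f"subject {subject}, {key.label} group {group}: "
                                f"missing gesture {gesture}"
                            )
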