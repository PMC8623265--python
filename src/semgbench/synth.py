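"""Synthetic surface-EMG generator.

Real sEMG under an isometric gesture is well approximated, for the
purposes of amplitude and spectral statistics, by bandlimited Gaussian
noise: each channel gets zero-mean noise shaped to a gesture- and
muscle-specific band inside 20-500 Hz and scaled by a gesture-specific
activation gain. That minimal model determines every statistic the
downstream analysis consumes (RMS, waveform length, thresholded
zero crossings and slope-sign changes, Welch PSD, mean power
frequency), so it is the generative model used here.

Condition effects are layered on top of the stationary core:

* **Muscle fatigue** (class ``b``) multiplies amplitudes by ``alpha >= 1``
  and compresses the spectral band by ``kappa <= 1`` — the classic
  fatigue signature (RMS up, mean power frequency down, power spectrum
  shifted towards low frequencies).
* **Forearm angle** perturbs per-channel gains (in a fixed
  pseudo-random per-gesture direction, proportional to the offset from
  the 45-degree reference) and rotates the channel space proportionally
  to the angle above 30 degrees, so the distribution gap between two
  angles grows with their angular distance.
* **Acquisition day** drifts gains and rotates the channel space
  proportionally to the day index (electrode repositioning between
  sessions changes which muscle each electrode sees — a gain/cross-talk
  effect, not a spectral one).

All randomness flows from one integer seed through counter-style
``SeedSequence`` spawn keys on (subject, gesture, condition, group), so
any single recording is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .core import (
    ALL_GESTURES,
    ANGLES,
    DAYS,
    FATIGUE_CLASSES,
    GESTURES,
    N_CHANNELS,
    REST_GESTURE,
    ConditionKey,
    DatasetRegistry,
    Recording,
)

logger = logging.getLogger(__name__)

# Fixed entropy for the gesture templates and condition-shift directions.
# Independent of the user seed: profiles are stable study "anatomy".
_TEMPLATE_ENTROPY = 771321

#: Amplitude scale (signal units ~ mV). Typical active-channel RMS then
#: sits in the tens-to-hundreds, so the 20-unit ZC/SSC threshold acts as
#: a genuine noise guard rather than a no-op or a wall.
AMPLITUDE_SCALE = 250.0
_REST_LEVEL = 0.04  # per-channel activation of RE, fraction of AMPLITUDE_SCALE
_ACTIVATION_FLOOR = 0.4  # every electrode sits over partly active muscle

_REFERENCE_ANGLE = 45  # angle with zero gain perturbation
_BASE_ANGLE = 30       # angle with zero cross-talk rotation
_DAY_INDEX = {d: i for i, d in enumerate(DAYS)}


@dataclass(frozen=True)
class GestureProfile:
    """Per-gesture channel activation and spectral shape.

    ``activation`` is the target per-channel RMS (signal units);
    ``spectral_center`` / ``spectral_width`` (Hz) define the band the
    channel's noise is shaped to.
    """

    gesture_id: str
    activation: np.ndarray
    spectral_center: np.ndarray
    spectral_width: np.ndarray

    def __post_init__(self) -> None:
        for name in ("activation", "spectral_center", "spectral_width"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.activation < 0):
            raise ValueError("activation entries must be >= 0")
        if np.any((self.spectral_center <= 20) | (self.spectral_center >= 500)):
            raise ValueError("spectral_center must lie strictly inside (20, 500) Hz")
        if np.any(self.spectral_width <= 0):
            raise ValueError("spectral_width must be positive")


@dataclass(frozen=True)
class ConditionShift:
    """Magnitudes of the three condition effects.

    All magnitudes are relative; every shift vanishes at zero condition
    gap (class ``a``, 45 degrees, day A). Defaults are ordered so the
    induced feature-distribution shift ranks day > angle > fatigue.
    """

    fatigue_amp_gain: float = 1.4      # alpha, applied in class b
    fatigue_freq_compress: float = 0.7  # kappa, applied in class b
    angle_perturb_scale: float = 0.008  # relative gain change per degree from 45
    angle_mixing: float = 0.016         # channel rotation per degree of angle gap
    day_gain_drift: float = 0.30        # relative gain drift per day gap
    day_mixing: float = 0.65            # channel rotation per day gap
    noise_floor: float = 3.0            # additive bandlimited noise RMS, signal units

    def __post_init__(self) -> None:
        if self.fatigue_amp_gain < 1:
            raise ValueError("fatigue_amp_gain must be >= 1 (fatigue raises RMS)")
        if not 0 < self.fatigue_freq_compress <= 1:
            raise ValueError("fatigue_freq_compress must be in (0, 1]")
        for name in (
            "angle_perturb_scale",
            "angle_mixing",
            "day_gain_drift",
            "day_mixing",
            "noise_floor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


SHIFT_PRESETS: Dict[str, ConditionShift] = {
    "default": ConditionShift(),
    "none": ConditionShift(
        fatigue_amp_gain=1.0,
        fatigue_freq_compress=1.0,
        angle_perturb_scale=0.0,
        angle_mixing=0.0,
        day_gain_drift=0.0,
        day_mixing=0.0,
    ),
    "strong": ConditionShift(
        fatigue_amp_gain=1.8,
        fatigue_freq_compress=0.5,
        angle_perturb_scale=0.014,
        angle_mixing=0.030,
        day_gain_drift=0.5,
        day_mixing=1.0,
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Acquisition-protocol parameters of the emulated study."""

    sampling_rate: float = 2000.0
    duration_a: float = 5.0    # seconds per rested (class a) trial
    duration_b: float = 15.0   # seconds per sustained fatigue (class b) trial
    n_groups: int = 5
    days: Tuple[str, ...] = DAYS
    fatigue_classes: Tuple[str, ...] = FATIGUE_CLASSES
    angles: Tuple[int, ...] = ANGLES
    gestures: Tuple[str, ...] = ALL_GESTURES
    separation: float = 1.0    # scales inter-gesture template distance
    # Trial-to-trial variability of effort and spectral content — the
    # within-class spread real repeated gestures show even under fixed
    # conditions. Effort variation is mostly common-mode (pressing
    # harder raises all muscles together): a scalar lognormal gain per
    # trial, plus a smaller independent per-channel residual, plus a
    # spectral wobble of the band centers (Hz).
    trial_effort_jitter: float = 0.08
    trial_gain_jitter: float = 0.04
    # Whole-spectrum scale wobble per trial (common to all channels —
    # conduction-velocity variation compresses or expands the spectrum
    # as a whole) plus a smaller independent per-channel center wobble.
    trial_spec_jitter: float = 0.06
    trial_center_jitter_hz: float = 6.0
    # Muscle state varies between trials along the fatigue axis: the
    # effective amplitude gain and frequency compression of a trial are
    # 1 + (alpha-1)*v and 1 - (1-kappa)*v, where the depth v ~ N(1, sd_b)
    # for sustained class-b trials and v ~ N(0, sd_a) for rested class-a
    # trials (mild spontaneous variation about the rested state), each
    # clipped symmetrically about its mean so the across-trial means
    # stay exactly alpha/kappa (class b) and 1/1 (class a).
    fatigue_depth_jitter: float = 0.20
    rest_depth_jitter: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.sampling_rate <= 1000:
            raise ValueError("sampling_rate must exceed 2x the 500 Hz band edge")

    def duration(self, fatigue: str) -> float:
        return self.duration_a if fatigue == "a" else self.duration_b


@dataclass(frozen=True)
class SubjectProfile:
    """A subject: deterministic per-gesture jitter around the templates."""

    subject_id: str
    base_seed: int

    def jitter(self, gesture_id: str) -> Tuple[np.ndarray, np.ndarray]:
        """(multiplicative activation jitter, additive center jitter in Hz)."""
        gi = ALL_GESTURES.index(gesture_id)
        rng = np.random.default_rng(
            np.random.SeedSequence(self.base_seed, spawn_key=(97, gi))
        )
        amp = 1.0 + 0.05 * rng.standard_normal(N_CHANNELS)
        center = 5.0 * rng.standard_normal(N_CHANNELS)
        return np.clip(amp, 0.5, 1.5), center


def make_subjects(n: int, seed: int = 0) -> List[SubjectProfile]:
    """Build ``n`` subjects with seeds derived deterministically from ``seed``."""
    ss = np.random.SeedSequence(seed, spawn_key=(11,))
    seeds = ss.generate_state(max(n, 1)) % (2**31)
    return [SubjectProfile(f"S{i + 1}", int(seeds[i])) for i in range(n)]


def default_profiles(separation: float = 1.0) -> Dict[str, GestureProfile]:
    """Fixed pseudo-random gesture templates.

    ``separation`` scales every template's distance from the
    across-gesture mean (activation pattern and spectral center alike):
    0 collapses all gestures onto one distribution, larger values make
    them easier to tell apart. The rest gesture RE keeps a strictly
    smaller total activation than any analyzed gesture.
    """
    rng = np.random.default_rng(np.random.SeedSequence(_TEMPLATE_ENTROPY, spawn_key=(1,)))
    # Activation patterns: every channel carries substantial activity
    # (each electrode sits over partly recruited forearm muscle, so
    # per-channel RMS stays well above the 20-unit noise threshold);
    # gestures differ in how that activity is distributed across the
    # four muscles. Templates are a maximin design: the best-spread of
    # many random pattern sets, so no two gestures nearly coincide.
    best, best_score = None, -np.inf
    for _ in range(200):
        cand = rng.dirichlet(np.full(N_CHANNELS, 0.8), size=len(GESTURES))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        dists = np.linalg.norm(cand[:, None] - cand[None, :], axis=-1)
        score = np.min(dists[np.triu_indices(len(GESTURES), 1)])
        if score > best_score:
            best, best_score = cand, score
    raw = best
    mean_dir = raw.mean(axis=0)
    # Spectral bands are muscle-specific with only mild gesture-to-gesture
    # offsets: the spectrum carries some class information but far less
    # than the recruitment pattern, as in real multi-muscle montages.
    base_center = rng.uniform(100.0, 140.0, size=N_CHANNELS)
    center_offsets = rng.uniform(-4.0, 4.0, size=(len(GESTURES), N_CHANNELS))
    base_width = rng.uniform(55.0, 75.0, size=N_CHANNELS)
    width_offsets = rng.uniform(-3.0, 3.0, size=(len(GESTURES), N_CHANNELS))

    profiles: Dict[str, GestureProfile] = {}
    for i, g in enumerate(GESTURES):
        act = AMPLITUDE_SCALE * (mean_dir + separation * (raw[i] - mean_dir))
        act = np.clip(act, 0.08 * AMPLITUDE_SCALE, None)
        cen = np.clip(base_center + separation * center_offsets[i], 60.0, 320.0)
        wid = np.clip(base_width + separation * width_offsets[i], 20.0, 120.0)
        profiles[g] = GestureProfile(g, act, cen, wid)
    profiles[REST_GESTURE] = GestureProfile(
        REST_GESTURE,
        np.full(N_CHANNELS, _REST_LEVEL * AMPLITUDE_SCALE),
        np.full(N_CHANNELS, 120.0),
        np.full(N_CHANNELS, 70.0),
    )
    return profiles


def _condition_directions(gesture_id: str) -> Tuple[np.ndarray, np.ndarray]:
    """Fixed per-gesture unit-range directions for angle and day gain shifts."""
    gi = ALL_GESTURES.index(gesture_id)
    rng = np.random.default_rng(np.random.SeedSequence(_TEMPLATE_ENTROPY, spawn_key=(2, gi)))
    angle_dir = rng.uniform(-1.0, 1.0, N_CHANNELS)
    day_dir = rng.uniform(-1.0, 1.0, N_CHANNELS)
    return angle_dir, day_dir


def _mixing_generator(kind: int) -> np.ndarray:
    """Fixed skew-symmetric cross-talk generator (kind 0: day, kind 1: angle).

    Channel mixing is applied as the orthogonal map ``expm(c * A)``: a
    rotation of the channel space. Electrode repositioning re-weights
    which muscle each electrode sees without creating or destroying
    signal energy, and a rotation keeps every condition equally
    separable intrinsically — only the train/test mismatch grows with
    the condition gap.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(_TEMPLATE_ENTROPY, spawn_key=(3, kind))
    )
    m = rng.standard_normal((N_CHANNELS, N_CHANNELS))
    a = m - m.T
    return a / np.linalg.norm(a)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise shaped to [low, high] Hz (4th-order Butterworth)."""
    nyq = fs / 2.0
    low = max(low, 1.0)
    high = min(high, 0.999 * nyq)
    if high <= low:  # degenerate band after compression: keep a sliver
        low, high = 0.8 * high, high
    sos = sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    r = np.sqrt(np.mean(x**2))
    return x / r if r > 0 else x


def generate_recording(
    subject: SubjectProfile,
    gesture_id: str,
    condition: ConditionKey,
    group: int,
    config: GeneratorConfig | None = None,
    shift: ConditionShift | None = None,
    profiles: Dict[str, GestureProfile] | None = None,
) -> Recording:
    """Synthesize one gesture trial under the given condition.

    Per channel ``c``: ``x_c(t) = g_c * b_c(t) + noise_floor * w_c(t)``
    with ``b_c`` unit-RMS noise shaped to the (possibly
    fatigue-compressed) gesture band and
    ``g_c = activation_c * alpha^[fatigue] * (1 + angle term) * (1 + day term)``,
    then cross-channel mixing proportional to the day index.
    Deterministic given (subject, gesture, condition, group, seed).
    """
    config = config or GeneratorConfig()
    shift = shift or ConditionShift()
    if gesture_id not in ALL_GESTURES:
        raise ValueError(f"unknown gesture {gesture_id!r}; expected one of {ALL_GESTURES}")
    if not isinstance(condition, ConditionKey):
        condition = ConditionKey.from_label(str(condition))
    profiles = profiles or default_profiles(config.separation)
    prof = profiles[gesture_id]

    amp_jit, cen_jit = subject.jitter(gesture_id)
    fatigued = condition.fatigue == "b"
    day_gap = _DAY_INDEX[condition.day]
    angle_dir, day_dir = _condition_directions(gesture_id)
    angle_gap = condition.angle - _REFERENCE_ANGLE
    angle_term = shift.angle_perturb_scale * angle_gap * angle_dir
    day_term = shift.day_gain_drift * day_gap * day_dir
    gains = (
        prof.activation * amp_jit
        * np.clip(1.0 + angle_term, 0.1, None)
        * np.clip(1.0 + day_term, 0.1, None)
    )

    n = int(round(config.duration(condition.fatigue) * config.sampling_rate))
    rng = np.random.default_rng(
        np.random.SeedSequence(
            config.seed,
            spawn_key=(
                subject.base_seed,
                ALL_GESTURES.index(gesture_id),
                _DAY_INDEX[condition.day],
                FATIGUE_CLASSES.index(condition.fatigue),
                int(condition.angle),
                int(group),
            ),
        )
    )
    # trial-to-trial variability: common-mode effort, per-channel gain
    # residual, spectral wobble, and muscle-state (fatigue-axis) depth
    effort = np.exp(config.trial_effort_jitter * rng.standard_normal())
    trial_gain = effort * np.exp(
        config.trial_gain_jitter * rng.standard_normal(N_CHANNELS)
    )
    spec_scale = np.exp(config.trial_spec_jitter * rng.standard_normal())
    trial_center = config.trial_center_jitter_hz * rng.standard_normal(N_CHANNELS)
    mean_depth = 1.0 if fatigued else 0.0
    sd = config.fatigue_depth_jitter if fatigued else config.rest_depth_jitter
    depth = float(
        np.clip(
            mean_depth + sd * rng.standard_normal(),
            mean_depth - 3 * sd,
            mean_depth + 3 * sd,
        )
    )
    alpha = 1.0 + (shift.fatigue_amp_gain - 1.0) * depth
    kappa = 1.0 - (1.0 - shift.fatigue_freq_compress) * depth
    gains = gains * trial_gain * alpha
    x = np.empty((N_CHANNELS, n))
    for c in range(N_CHANNELS):
        center = (prof.spectral_center[c] + cen_jit[c] + trial_center[c]) * kappa * spec_scale
        half = 0.5 * prof.spectral_width[c] * kappa * spec_scale
        lo, hi = max(21.0, center - half), min(499.0, center + half)
        x[c] = gains[c] * _bandlimited_noise(rng, n, config.sampling_rate, lo, hi)
    if shift.noise_floor > 0:
        for c in range(N_CHANNELS):
            x[c] += shift.noise_floor * _bandlimited_noise(
                rng, n, config.sampling_rate, 20.0, 499.0
            )
    gen = np.zeros((N_CHANNELS, N_CHANNELS))
    if shift.day_mixing > 0 and day_gap > 0:
        gen += shift.day_mixing * day_gap * _mixing_generator(0)
    rot_gap = condition.angle - _BASE_ANGLE
    if shift.angle_mixing > 0 and rot_gap != 0:
        # rotation accumulates in one direction with increasing angle,
        # so the cross-talk mismatch between two angles grows with
        # their angular distance (as the day rotation does with days)
        gen += shift.angle_mixing * rot_gap * _mixing_generator(1)
    if np.any(gen):
        x = sla.expm(gen) @ x

    return Recording(
        samples=x,
        sampling_rate=config.sampling_rate,
        gesture_id=gesture_id,
        subject_id=subject.subject_id,
        condition=condition,
        group=group,
    )


def generate_study(
    subjects: Sequence[SubjectProfile],
    config: GeneratorConfig | None = None,
    shift: ConditionShift | None = None,
) -> DatasetRegistry:
    """Generate the full factorial study for the given subjects.

    For each subject: every (day x fatigue class x angle) dataset class
    in the config (18 at the full design), ``n_groups`` groups each,
    one recording per gesture (12 including RE).
    """
    if not subjects:
        raise ValueError("subject list must be non-empty")
    config = config or GeneratorConfig()
    shift = shift or ConditionShift()
    profiles = default_profiles(config.separation)
    registry = DatasetRegistry()
    for subject in subjects:
        for day in config.days:
            for fatigue in config.fatigue_classes:
                for angle in config.angles:
                    key = ConditionKey(day, fatigue, angle)
                    for group in range(1, config.n_groups + 1):
                        for gesture in config.gestures:
                            registry.add(
                                generate_recording(
                                    subject, gesture, key, group, config, shift, profiles
                                )
                            )
    logger.info(
        "generated study: %d subjects, %d recordings", len(subjects), len(registry)
    )
    return registry
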