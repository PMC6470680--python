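"""Synthetic race-walking IMU cohort generator.

Emulates the acquisition protocol of an instrumented race-walking session:
seven inertial units (pelvis, left/right thigh, shank, foot), each providing
tri-axial linear acceleration [m/s^2] and angular velocity [deg/s] at 60 Hz,
while the athlete covers three consecutive laps -- one per condition: regular
race walking, loss-of-contact (LC) faults, and knee-bent (KB) faults.  A
hand-held "coach" unit records a vertical-acceleration channel that flips the
sign of its gravity component at every condition transition, providing the
reference for labelling.

Signal model
------------
Gait signals are quasi-periodic, so every channel is represented by a
truncated Fourier series over the stride cycle (phase ``phi`` in [0, 1),
heel strike of the ipsilateral foot at ``phi = 0``).  Condition effects are
additive template modifications scaled linearly by the class-separation
parameter ``delta``:

* LC adds a free-fall-like dip toward ``-g`` on the vertical acceleration of
  pelvis and shanks during two flight windows per stride (one per step);
* KB adds amplitude/phase perturbations to the sagittal channels of shank and
  thigh around mid-stance.

Right-side templates equal the left-side ones shifted by half a cycle
(left/right symmetry of race walking).  Inter-athlete variability is a
multiplicative perturbation of the harmonic amplitudes.

Axis convention: ``x`` antero-posterior, ``y`` medio-lateral, ``z`` vertical;
the sagittal-plane angular velocity (rotation about the medio-lateral axis)
is therefore ``gyr_y``.  The shank sagittal template is built with one
dominant positive mid-swing peak flanked by two negative peaks so that
shank-gyro heel-strike detection is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ConfigurationError, InputError

#: segment blocks in canonical order (7 units, 42 kinematic channels)
SEGMENT_SIDES: tuple[tuple[str, str], ...] = (
    ("pelvis", "center"),
    ("thigh", "left"),
    ("thigh", "right"),
    ("shank", "left"),
    ("shank", "right"),
    ("foot", "left"),
    ("foot", "right"),
)
CHANNELS: tuple[str, ...] = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")
CONDITIONS: tuple[str, ...] = ("regular", "LC", "KB")

SAGITTAL_GYRO = "gyr_y"
VERTICAL_ACC = "acc_z"
GRAVITY = 9.81  # m/s^2

_GRID = 240  # samples per cycle used when projecting waveforms onto harmonics
_TEMPLATE_SEED = 1234  # the base waveform bank is a fixed part of the model


def channel_key(segment: str, side: str, channel: str) -> str:
    return f"{segment}_{side}_{channel}"


ALL_CHANNEL_KEYS: tuple[str, ...] = tuple(
    channel_key(seg, side, ch) for seg, side in SEGMENT_SIDES for ch in CHANNELS
)


@dataclass(frozen=True)
class NoiseConfig:
    """Additive white-noise standard deviations per channel family."""

    acc: float = 0.3  # m/s^2
    gyr: float = 5.0  # deg/s


@dataclass(frozen=True)
class GeneratorConfig:
    n_athletes: int = 8
    n_repetitions: int = 2
    conditions_order: tuple[str, ...] = CONDITIONS
    strides_per_condition: int = 120
    sampling_rate: float = 60.0
    stride_duration_mean: float = 0.70  # s
    stride_duration_cv: float = 0.05
    n_harmonics: int = 6
    class_separation: float = 1.0  # delta >= 0
    athlete_variability: float = 0.10
    noise_sd: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_athletes < 1 or self.n_repetitions < 1:
            raise ConfigurationError("athlete and repetition counts must be >= 1")
        if self.strides_per_condition < 1:
            raise ConfigurationError("strides_per_condition must be >= 1")
        if self.n_harmonics < 1:
            raise ConfigurationError("n_harmonics must be >= 1")
        if self.class_separation < 0:
            raise ConfigurationError("class_separation (delta) must be >= 0")
        if self.stride_duration_mean <= 0 or self.sampling_rate <= 0:
            raise ConfigurationError("stride duration and sampling rate must be > 0")
        if self.stride_duration_cv < 0 or self.athlete_variability < 0:
            raise ConfigurationError("variability fractions must be >= 0")
        if not self.conditions_order:
            raise ConfigurationError("conditions_order must not be empty")
        unknown = set(self.conditions_order) - set(CONDITIONS)
        if unknown:
            raise ConfigurationError(f"unknown condition labels: {sorted(unknown)}")
        if len(set(self.conditions_order)) != len(self.conditions_order):
            raise ConfigurationError("conditions_order contains duplicates")


@dataclass
class AthleteProfile:
    """Per-athlete harmonic templates: (segment, side, channel) -> (n_conditions, H+1)
    complex Fourier coefficients, rows ordered as ``conditions_order``."""

    athlete_id: str
    athlete_index: int
    stride_duration_mean: float
    conditions_order: tuple[str, ...]
    templates: dict[tuple[str, str, str], np.ndarray]


@dataclass
class SessionRecording:
    athlete_id: str
    repetition: int
    sampling_rate: float
    channels: dict[str, np.ndarray]  # 42 kinematic channels keyed segment_side_channel
    coach: np.ndarray  # vertical acceleration of the referee unit [m/s^2]

    @property
    def n_samples(self) -> int:
        return len(self.coach)

    def segment_channel(self, segment: str, side: str, channel: str) -> np.ndarray:
        return self.channels[channel_key(segment, side, channel)]

    def validate(self) -> None:
        if set(self.channels) != set(ALL_CHANNEL_KEYS):
            raise InputError("recording must carry exactly the 42 kinematic channels")
        lengths = {len(v) for v in self.channels.values()} | {len(self.coach)}
        if len(lengths) != 1:
            raise InputError("all channels must share one length")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be > 0")


@dataclass
class GroundTruth:
    """Planted events of one synthetic session.

    ``heel_strikes[side]`` holds the true heel-strike sample indices; per side
    and condition there are ``strides_per_condition`` stride-start events (the
    closing boundary of the last stride of the session falls outside the
    recording and is dropped).  ``transitions`` are the condition-change
    sample indices; ``conditions`` the block order.
    """

    transitions: np.ndarray
    conditions: tuple[str, ...]
    heel_strikes: dict[str, np.ndarray]
    n_samples: int
    sampling_rate: float

    def condition_at(self, samples: np.ndarray | int) -> np.ndarray:
        """True condition label for each sample index."""
        idx = np.searchsorted(self.transitions, np.atleast_1d(samples), side="right")
        return np.asarray(self.conditions, dtype=object)[idx]


# ---------------------------------------------------------------------------
# template bank
# ---------------------------------------------------------------------------

def _periodic_bump(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    d = phi - center
    d = d - np.round(d)
    return np.exp(-0.5 * (d / width) ** 2)


def _project(y: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Complex Fourier coefficients c_0..c_H of a cycle sampled on the grid."""
    return np.fft.rfft(y) / len(y)


def evaluate_template(coeffs: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Reconstruct the waveform at cycle phases ``phi`` (cycles, not radians)."""
    coeffs = np.asarray(coeffs)
    k = np.arange(coeffs.shape[-1])
    weights = np.ones_like(k, dtype=float)
    weights[1:] = 2.0
    basis = np.exp(2j * np.pi * np.outer(np.atleast_1d(phi), k))
    return (basis @ (coeffs * weights)).real


@lru_cache(maxsize=8)
def _template_bank(n_harmonics: int):
    """Base (left-side) waveform coefficients and condition modifiers.

    Returns ``(base, modifiers)`` where both map ``(segment, channel)`` to a
    complex coefficient array; ``modifiers`` is keyed by condition label and
    holds the *unit* (delta = 1) additive template differences.
    """
    phi = np.arange(_GRID) / _GRID
    rng = np.random.default_rng(_TEMPLATE_SEED)
    keep = n_harmonics + 1

    base: dict[tuple[str, str], np.ndarray] = {}
    for segment, side in SEGMENT_SIDES:
        if side == "right":
            continue  # right templates are the left ones shifted by half a cycle
        for chan in CHANNELS:
            if segment in ("shank", "foot") and chan == SAGITTAL_GYRO:
                amp = 380.0 if segment == "shank" else 430.0
                y = (
                    amp * _periodic_bump(phi, 0.80, 0.06)
                    - 150.0 * _periodic_bump(phi, 0.64, 0.05)
                    - 240.0 * _periodic_bump(phi, 0.0, 0.05)
                    + 25.0 * np.sin(2 * np.pi * phi)
                )
            elif chan == VERTICAL_ACC:
                # two support phases per stride -> dominant second harmonic
                a2 = rng.uniform(2.0, 4.0)
                a1 = rng.uniform(0.5, 1.5)
                p2, p1 = rng.uniform(0, 2 * np.pi, 2)
                y = (
                    GRAVITY
                    + a2 * np.sin(4 * np.pi * phi + p2)
                    + a1 * np.sin(2 * np.pi * phi + p1)
                )
            else:
                scale = 2.5 if chan.startswith("acc") else 80.0
                y = np.zeros_like(phi)
                for k in (1, 2, 3):
                    y += (
                        rng.uniform(0.3, 1.0)
                        * scale
                        / k
                        * np.sin(2 * np.pi * k * phi + rng.uniform(0, 2 * np.pi))
                    )
            base[(segment, chan)] = _project(y, n_harmonics)[:keep]

    # loss of contact: free-fall dip toward -g in two flight windows per stride
    flight = -GRAVITY * (
        _periodic_bump(phi, 0.15, 0.05) + _periodic_bump(phi, 0.65, 0.05)
    )
    lc = {
        ("pelvis", VERTICAL_ACC): _project(flight, n_harmonics)[:keep],
        ("shank", VERTICAL_ACC): _project(flight, n_harmonics)[:keep],
    }
    # knee bent: mid-stance amplitude/phase perturbation of sagittal channels
    kb = {
        ("shank", SAGITTAL_GYRO): _project(
            90.0 * _periodic_bump(phi, 0.30, 0.08)
            - 70.0 * _periodic_bump(phi, 0.45, 0.08),
            n_harmonics,
        )[:keep],
        ("thigh", SAGITTAL_GYRO): _project(
            60.0 * _periodic_bump(phi, 0.35, 0.10), n_harmonics
        )[:keep],
        ("shank", "acc_x"): _project(
            2.5 * _periodic_bump(phi, 0.35, 0.10)
            - 1.5 * _periodic_bump(phi, 0.50, 0.10),
            n_harmonics,
        )[:keep],
        ("thigh", "acc_x"): _project(
            1.8 * _periodic_bump(phi, 0.40, 0.12), n_harmonics
        )[:keep],
    }
    modifiers = {"regular": {}, "LC": lc, "KB": kb}
    return base, modifiers


# ---------------------------------------------------------------------------
# profile and session synthesis
# ---------------------------------------------------------------------------

def make_profile(config: GeneratorConfig, athlete_index: int) -> AthleteProfile:
    """Deterministic per-athlete template set (fixed seed + index)."""
    if not 0 <= athlete_index < config.n_athletes:
        raise ConfigurationError(
            f"athlete_index {athlete_index} outside 0..{config.n_athletes - 1}"
        )
    base, modifiers = _template_bank(config.n_harmonics)
    rng = np.random.default_rng([config.seed, 0, athlete_index])
    n_coeffs = config.n_harmonics + 1
    var = config.athlete_variability
    delta = config.class_separation

    stride_mean = config.stride_duration_mean * float(
        np.clip(1.0 + 0.05 * rng.standard_normal(), 0.8, 1.2)
    )

    left: dict[tuple[str, str], np.ndarray] = {}
    for (segment, chan), base_c in sorted(base.items()):
        f_base = np.clip(1.0 + var * rng.standard_normal(n_coeffs), 0.1, None)
        rows = []
        for cond in config.conditions_order:
            mod_c = modifiers[cond].get((segment, chan))
            if mod_c is None:
                rows.append(base_c * f_base)
            else:
                f_mod = np.clip(1.0 + var * rng.standard_normal(n_coeffs), 0.1, None)
                rows.append(base_c * f_base + delta * mod_c * f_mod)
        left[(segment, chan)] = np.asarray(rows)

    half_shift = (-1.0) ** np.arange(n_coeffs)  # exp(-i*pi*k): half-cycle delay
    templates: dict[tuple[str, str, str], np.ndarray] = {}
    for segment, side in SEGMENT_SIDES:
        for chan in CHANNELS:
            c = left[(segment, chan)]
            templates[(segment, side, chan)] = c * half_shift if side == "right" else c.copy()

    return AthleteProfile(
        athlete_id=f"ath{athlete_index:02d}",
        athlete_index=athlete_index,
        stride_duration_mean=stride_mean,
        conditions_order=tuple(config.conditions_order),
        templates=templates,
    )


def synthesize_coach_channel(
    transitions,
    n_samples: int,
    noise_sd: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vertical acceleration of the referee unit: +/-g, flipping at transitions."""
    transitions = np.asarray(transitions, dtype=int)
    if transitions.size and (
        np.any(np.diff(transitions) <= 0)
        or transitions[0] < 0
        or transitions[-1] >= n_samples
    ):
        raise InputError("transitions must be strictly increasing and < n_samples")
    flips = np.searchsorted(transitions, np.arange(n_samples), side="right")
    signal = GRAVITY * (-1.0) ** flips
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        signal = signal + rng.normal(0.0, noise_sd, n_samples)
    return signal


def synthesize_session(
    profile: AthleteProfile, repetition: int, config: GeneratorConfig
) -> tuple[SessionRecording, GroundTruth]:
    """One athlete-repetition: contiguous condition blocks, planted events."""
    rng = np.random.default_rng([config.seed, 1, profile.athlete_index, repetition])
    fs = config.sampling_rate
    n = config.strides_per_condition
    mean = profile.stride_duration_mean

    durations = []
    for _ in config.conditions_order:
        d = mean * (1.0 + config.stride_duration_cv * rng.standard_normal(n))
        durations.append(np.clip(d, 0.5 * mean, 1.5 * mean))
    durations = np.concatenate(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    total = float(np.sum(durations))
    n_samples = int(np.floor(total * fs))
    t = np.arange(n_samples) / fs

    stride_idx = np.searchsorted(starts, t, side="right") - 1
    phase = (t - starts[stride_idx]) / durations[stride_idx]
    cycle = stride_idx + phase
    cond_of_stride = np.repeat(np.arange(len(config.conditions_order)), n)
    cond_idx = cond_of_stride[stride_idx]

    n_coeffs = config.n_harmonics + 1
    k = np.arange(n_coeffs)
    weights = np.ones(n_coeffs)
    weights[1:] = 2.0
    # the half-cycle right/left shift is baked into the profile templates,
    # so one basis serves every side
    basis = np.exp(2j * np.pi * np.outer(cycle, k))

    channels: dict[str, np.ndarray] = {}
    for segment, side in SEGMENT_SIDES:
        for chan in CHANNELS:
            coeffs = profile.templates[(segment, side, chan)]  # (n_cond, H+1)
            per_cond = (basis @ (coeffs * weights).T).real  # (T, n_cond)
            y = per_cond[np.arange(n_samples), cond_idx]
            sd = config.noise_sd.acc if chan.startswith("acc") else config.noise_sd.gyr
            if sd > 0:
                y = y + rng.normal(0.0, sd, n_samples)
            channels[channel_key(segment, side, chan)] = y

    block_ends = np.cumsum(durations.reshape(len(config.conditions_order), n).sum(axis=1))
    transitions = np.array(
        [int(round(te * fs)) for te in block_ends[:-1] if round(te * fs) < n_samples],
        dtype=int,
    )
    coach = synthesize_coach_channel(transitions, n_samples, config.noise_sd.acc, rng)

    left_times = np.concatenate([starts, [total]])
    left_hs = np.round(left_times * fs).astype(int)
    left_hs = left_hs[left_hs < n_samples]
    right_times = starts + 0.5 * durations
    right_hs = np.round(right_times * fs).astype(int)
    right_hs = right_hs[right_hs < n_samples]

    recording = SessionRecording(
        athlete_id=profile.athlete_id,
        repetition=repetition,
        sampling_rate=fs,
        channels=channels,
        coach=coach,
    )
    truth = GroundTruth(
        transitions=transitions,
        conditions=tuple(config.conditions_order),
        heel_strikes={"left": left_hs, "right": right_hs},
        n_samples=n_samples,
        sampling_rate=fs,
    )
    return recording, truth


def generate_cohort(
    config: GeneratorConfig,
) -> dict[tuple[str, int], tuple[SessionRecording, GroundTruth]]:
    """All (athlete, repetition) sessions of one synthetic study."""
    cohort: dict[tuple[str, int], tuple[SessionRecording, GroundTruth]] = {}
    for i in range(config.n_athletes):
        profile = make_profile(config, i)
        for rep in range(1, config.n_repetitions + 1):
            cohort[(profile.athlete_id, rep)] = synthesize_session(profile, rep, config)
    return cohort
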