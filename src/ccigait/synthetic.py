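"""Synthetic raw EMG + foot-IMU gait trials.

Generates surface EMG (2000 Hz, four lower-limb muscles) and foot vertical
acceleration (142 Hz) for treadmill walking trials with the statistical
structure the downstream analysis assumes:

* gait-phase-locked muscle bursts (Gaussian bumps on the 0-1 stride-phase
  circle, wrapped across the 100% -> 0% boundary),
* a tonic co-activation baseline that is elevated in the cerebral-palsy (CP)
  population relative to typically developing (TD) children,
* multiplicative amplitude effects of treadmill environment (aquatic "Wet"
  trials attenuated relative to "Dry") and belt speed (Slow/Normal/Fast),
* lognormal stride-time variability with occasional lengthened outlier
  strides,
* a dominant positive acceleration peak at every initial contact.

Raw EMG is synthesised as activation-profile amplitude-modulated white noise
(plus a small additive noise floor), so that rectification and low-pass
filtering recover the generating profile up to the constant sqrt(2/pi) --
the pipeline is exercised on realistic raw signals, never on envelopes
directly.

All randomness flows through ``numpy.random.Generator``; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

MUSCLES: tuple[str, ...] = ("TA", "MG", "RF", "ST")
POPULATIONS: tuple[str, ...] = ("TD", "CP")
ENVIRONMENTS: tuple[str, ...] = ("Dry", "Wet")
SPEEDS: tuple[str, ...] = ("Slow", "Normal", "Fast")


def _default_burst_centers() -> dict[str, tuple[float, ...]]:
    # textbook gait phases: TA active around initial contact and through swing,
    # MG through stance, RF at loading response and early swing, ST around
    # terminal swing wrapping into initial contact
    return {
        "TA": (0.05, 0.80),
        "MG": (0.30,),
        "RF": (0.07, 0.625),
        "ST": (0.975,),
    }


def _default_burst_widths() -> dict[str, tuple[float, ...]]:
    return {
        "TA": (0.035, 0.10),
        "MG": (0.10,),
        "RF": (0.05, 0.04),
        "ST": (0.06,),
    }


def _default_burst_amplitudes() -> dict[str, tuple[float, ...]]:
    return {
        "TA": (0.6, 1.0),
        "MG": (1.0,),
        "RF": (1.0, 0.6),
        "ST": (1.0,),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 15 TD and 10 CP participants,
    both limbs instrumented, ~3-minute trials (≈160 strides at ~1.1 s per
    stride), EMG at 2000 Hz and foot IMU at 142 Hz. Effect magnitudes
    (environment/speed amplitude factors, CP baseline elevation) are invented
    but directionally faithful: Wet < Dry amplitude, Fast > Slow amplitude,
    CP > TD tonic co-activation.
    """

    n_participants_td: int = 15
    n_participants_cp: int = 10
    limbs: tuple[str, ...] = ("left", "right")
    strides_per_trial: int = 160
    stride_time_mean_s: float = 1.1
    stride_time_cv: float = 0.05
    outlier_stride_prob: float = 0.02
    outlier_stride_scale: float = 1.8
    emg_rate_hz: float = 2000.0
    imu_rate_hz: float = 142.0
    burst_centers: Mapping[str, tuple[float, ...]] = field(
        default_factory=_default_burst_centers
    )
    burst_widths: Mapping[str, tuple[float, ...]] = field(
        default_factory=_default_burst_widths
    )
    burst_amplitudes: Mapping[str, tuple[float, ...]] = field(
        default_factory=_default_burst_amplitudes
    )
    coactivation_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"TD": 0.05, "CP": 0.15}
    )
    env_amplitude_factor: float = 0.65
    speed_amplitude_factors: Mapping[str, float] = field(
        default_factory=lambda: {"Slow": 0.85, "Normal": 1.0, "Fast": 1.2}
    )
    participant_offset_sd: float = 0.10
    noise_sd: float = 0.01
    accel_peak_g: float = 2.0
    accel_noise_sd_g: float = 0.1
    ic_pulse_width_s: float = 0.05
    lead_in_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants_td < 0 or self.n_participants_cp < 0:
            raise ValueError("participant counts must be nonnegative")
        if self.strides_per_trial <= 0:
            raise ValueError("strides_per_trial must be positive")
        if self.stride_time_mean_s <= 0:
            raise ValueError("stride_time_mean_s must be positive")
        if self.stride_time_cv < 0:
            raise ValueError("stride_time_cv must be nonnegative")
        if not 0.0 <= self.outlier_stride_prob <= 1.0:
            raise ValueError("outlier_stride_prob must be in [0, 1]")
        if self.emg_rate_hz <= 0 or self.imu_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.noise_sd < 0 or self.accel_noise_sd_g < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.participant_offset_sd < 0:
            raise ValueError("participant_offset_sd must be nonnegative")
        for name, table in (
            ("burst_centers", self.burst_centers),
            ("burst_widths", self.burst_widths),
            ("burst_amplitudes", self.burst_amplitudes),
        ):
            if set(table) != set(MUSCLES):
                raise ValueError(
                    f"{name} must be given for exactly the muscles {MUSCLES}"
                )
        for m in MUSCLES:
            n = len(self.burst_centers[m])
            if len(self.burst_widths[m]) != n or len(self.burst_amplitudes[m]) != n:
                raise ValueError(f"burst parameter lists for {m} differ in length")
            if any(w <= 0 for w in self.burst_widths[m]):
                raise ValueError("burst widths must be positive")
            if any(a < 0 for a in self.burst_amplitudes[m]):
                raise ValueError("burst amplitudes must be nonnegative")
        for pop in POPULATIONS:
            if self.coactivation_baseline.get(pop, -1.0) < 0:
                raise ValueError(
                    "coactivation_baseline must map TD and CP to nonnegative values"
                )


@dataclass(frozen=True)
class TrialCondition:
    """Labels identifying one walking trial of one instrumented limb."""

    participant_id: str
    limb: str
    population: str
    environment: str
    speed: str

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.speed not in SPEEDS:
            raise ValueError(f"unknown speed {self.speed!r}")

    @property
    def trial_id(self) -> str:
        return f"{self.participant_id}-{self.limb}-{self.environment}-{self.speed}"


@dataclass(frozen=True)
class RawTrial:
    """Raw multi-channel EMG and foot vertical acceleration for one trial."""

    trial_id: str
    participant_id: str
    limb: str
    population: str
    environment: str
    speed: str
    emg: Mapping[str, np.ndarray]  # volts (arbitrary scale), at emg_rate_hz
    accel_vertical: np.ndarray  # g, at imu_rate_hz
    emg_rate_hz: float
    imu_rate_hz: float
    true_initial_contacts_s: np.ndarray  # ground truth, simulation only

    def __post_init__(self) -> None:
        lengths = {len(self.emg[m]) for m in self.emg}
        if len(lengths) != 1:
            raise ValueError("EMG series must have equal length across muscles")
        ics = np.asarray(self.true_initial_contacts_s)
        if ics.size >= 2 and not np.all(np.diff(ics) > 0):
            raise ValueError("true_initial_contacts_s must be strictly increasing")


def _condition_amplitude_factor(config: SimulationConfig, condition: TrialCondition) -> float:
    f = config.speed_amplitude_factors[condition.speed]
    if condition.environment == "Wet":
        f *= config.env_amplitude_factor
    return f


def make_activation_profile(
    muscle: str,
    config: SimulationConfig,
    condition: TrialCondition,
    amplitude_scale: float = 1.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Return the muscle's activation as a function of gait-phase fraction.

    The profile is the population's tonic co-activation baseline plus a sum
    of Gaussian bursts (centres/widths/amplitudes from the config), wrapped
    modulo 1 so swing-phase bursts continue smoothly across the stride
    boundary, all scaled by the environment and speed amplitude factors.
    ``amplitude_scale`` multiplies the burst amplitudes only (used for
    participant-level offsets); the baseline is left untouched so that
    per-muscle dynamic normalization does not cancel the offset.
    """
    if muscle not in MUSCLES:
        raise ValueError(f"unknown muscle {muscle!r}; expected one of {MUSCLES}")
    centers = np.asarray(config.burst_centers[muscle], dtype=float)
    widths = np.asarray(config.burst_widths[muscle], dtype=float)
    amps = np.asarray(config.burst_amplitudes[muscle], dtype=float) * amplitude_scale
    baseline = float(config.coactivation_baseline[condition.population])
    cond_factor = _condition_amplitude_factor(config, condition)

    def profile(phase: np.ndarray) -> np.ndarray:
        phase = np.mod(np.asarray(phase, dtype=float), 1.0)
        total = np.full_like(phase, baseline)
        for c, w, a in zip(centers, widths, amps):
            for k in (-1.0, 0.0, 1.0):  # wrap bursts across the stride boundary
                d = phase - c + k
                total += a * np.exp(-0.5 * (d / w) ** 2)
        return cond_factor * total

    return profile


def _draw_stride_durations(
    config: SimulationConfig, condition: TrialCondition, rng: np.random.Generator
) -> np.ndarray:
    # faster belt speeds shorten the stride time by the same factor that
    # raises burst amplitude
    mean_dur = config.stride_time_mean_s / config.speed_amplitude_factors[condition.speed]
    cv = config.stride_time_cv
    n = config.strides_per_trial
    if cv > 0:
        sigma2 = math.log1p(cv * cv)
        mu = math.log(mean_dur) - sigma2 / 2.0
        durations = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    else:
        durations = np.full(n, mean_dur)
    outlier = rng.random(n) < config.outlier_stride_prob
    return np.where(outlier, durations * config.outlier_stride_scale, durations)


def _phase_at(times: np.ndarray, ics: np.ndarray) -> np.ndarray:
    """Within-stride gait-phase fraction for each sample time."""
    durations = np.diff(ics)
    idx = np.clip(np.searchsorted(ics, times, side="right") - 1, 0, len(durations) - 1)
    return np.mod((times - ics[idx]) / durations[idx], 1.0)


def evaluate_profiles(
    config: SimulationConfig,
    condition: TrialCondition,
    ic_times: np.ndarray,
    rate_hz: float,
    amplitude_scales: Mapping[str, float] | None = None,
    t_end: float | None = None,
) -> dict[str, np.ndarray]:
    """Noise-free activation profiles sampled on the trial's time grid.

    Deterministic companion to :func:`simulate_trial` used to validate that
    segmentation + interpolation recover the generating waveform.
    """
    ics = np.asarray(ic_times, dtype=float)
    if t_end is None:
        t_end = float(ics[-1])
    times = np.arange(int(round(t_end * rate_hz))) / rate_hz
    phase = _phase_at(times, ics)
    scales = amplitude_scales or {}
    return {
        m: make_activation_profile(m, config, condition, scales.get(m, 1.0))(phase)
        for m in MUSCLES
    }


def simulate_trial(
    config: SimulationConfig,
    condition: TrialCondition,
    rng: np.random.Generator | int,
    amplitude_scales: Mapping[str, float] | None = None,
) -> RawTrial:
    """Simulate one treadmill walking trial.

    Stride durations are lognormal with the configured coefficient of
    variation; with probability ``outlier_stride_prob`` a stride is lengthened
    by ``outlier_stride_scale``. The trial starts at an initial contact after
    a short lead-in, and EMG/IMU streams share one clock. Raw EMG per muscle
    is the activation profile (at the sample's within-stride phase) amplitude-
    modulating unit white noise, plus an additive ``noise_sd`` floor. The
    accelerometer stream carries a half-sine (~50 ms) positive peak at every
    initial contact over low-amplitude noise.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    durations = _draw_stride_durations(config, condition, rng)
    ics = config.lead_in_s + np.concatenate([[0.0], np.cumsum(durations)])
    t_end = float(ics[-1]) + 2.0 * config.ic_pulse_width_s

    t_emg = np.arange(int(round(t_end * config.emg_rate_hz))) / config.emg_rate_hz
    phase = _phase_at(t_emg, ics)
    scales = amplitude_scales or {}
    emg: dict[str, np.ndarray] = {}
    for m in MUSCLES:
        prof = make_activation_profile(m, config, condition, scales.get(m, 1.0))(phase)
        emg[m] = prof * rng.standard_normal(t_emg.size) + config.noise_sd * rng.standard_normal(
            t_emg.size
        )

    t_imu = np.arange(int(round(t_end * config.imu_rate_hz))) / config.imu_rate_hz
    accel = config.accel_noise_sd_g * rng.standard_normal(t_imu.size)
    half = config.ic_pulse_width_s / 2.0
    for ic in ics:
        mask = np.abs(t_imu - ic) <= half
        accel[mask] += config.accel_peak_g * np.cos(
            np.pi * (t_imu[mask] - ic) / config.ic_pulse_width_s
        )

    return RawTrial(
        trial_id=condition.trial_id,
        participant_id=condition.participant_id,
        limb=condition.limb,
        population=condition.population,
        environment=condition.environment,
        speed=condition.speed,
        emg=emg,
        accel_vertical=accel,
        emg_rate_hz=config.emg_rate_hz,
        imu_rate_hz=config.imu_rate_hz,
        true_initial_contacts_s=ics,
    )


def participant_amplitude_scales(
    config: SimulationConfig, participant_index: int
) -> dict[str, float]:
    """Per-muscle multiplicative burst-amplitude offsets for one participant.

    Lognormal with log-SD ``participant_offset_sd``, shared across all of the
    participant's trials — the between-subject component a random-intercept
    model should absorb.
    """
    prng = np.random.default_rng([config.seed, 1_000_003, participant_index])
    if config.participant_offset_sd == 0:
        return {m: 1.0 for m in MUSCLES}
    draws = prng.normal(0.0, config.participant_offset_sd, size=len(MUSCLES))
    return {m: float(np.exp(d)) for m, d in zip(MUSCLES, draws)}


def simulate_cohort(config: SimulationConfig) -> list[RawTrial]:
    """Simulate the full crossed cohort.

    Every participant contributes, per instrumented limb, one trial in each
    of the 2 environments x 3 speeds cells. Trial count is
    (n_td + n_cp) * n_limbs * 6.
    """
    trials: list[RawTrial] = []
    pidx = 0
    for pop, count in (("TD", config.n_participants_td), ("CP", config.n_participants_cp)):
        for i in range(count):
            participant = f"{pop}{i + 1:02d}"
            scales = participant_amplitude_scales(config, pidx)
            for li, limb in enumerate(config.limbs):
                for ei, env in enumerate(ENVIRONMENTS):
                    for si, speed in enumerate(SPEEDS):
                        rng = np.random.default_rng([config.seed, pidx, li, ei, si])
                        cond = TrialCondition(participant, limb, pop, env, speed)
                        trials.append(simulate_trial(config, cond, rng, scales))
            pidx += 1
    return trials


def config_variant(config: SimulationConfig, **changes) -> SimulationConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **changes)
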