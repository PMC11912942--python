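"""Linear-envelope extraction and dynamic normalization of surface EMG.

The envelope pipeline is the standard clinical-gait chain: remove the DC
bias, full-wave rectify, then apply a zero-phase (forward-backward)
2nd-order Butterworth low-pass at 6 Hz. Envelopes are then *dynamically*
normalized: every muscle of every trial of a limb is divided by that
muscle's envelope maximum during the limb's Dry Fast-walking trial, the
condition expected to elicit the greatest activation. Values above 1 in
other trials are legitimate and preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .synthetic import MUSCLES, RawTrial


class MissingReferenceTrialError(ValueError):
    """The limb's trial set does not contain exactly one Dry Fast trial."""


class DeadChannelError(ValueError):
    """A muscle's reference envelope maximum is zero (dead channel)."""


@dataclass(frozen=True)
class EnvelopeTrial:
    """Per-muscle linear envelopes with the trial's condition labels.

    ``normalization_factor`` is None before dynamic normalization; afterwards
    it records, per muscle, the Dry-Fast envelope maximum used as divisor.
    """

    trial_id: str
    participant_id: str
    limb: str
    population: str
    environment: str
    speed: str
    envelopes: Mapping[str, np.ndarray]
    rate_hz: float
    normalization_factor: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for m, env in self.envelopes.items():
            if np.any(np.asarray(env) < 0):
                raise ValueError(f"envelope for {m} has negative values")


def linear_envelope(
    raw_emg: np.ndarray,
    rate_hz: float,
    cutoff_hz: float = 6.0,
    order: int = 2,
) -> np.ndarray:
    """Bias-removed, rectified, zero-phase low-pass filtered EMG.

    ``order`` is the order of each pass of the dual-pass Butterworth filter
    (effective order 2*order with zero phase lag). Edge effects are handled
    by reflective padding of length 3*order. Negative filter undershoot is
    clipped to zero because the co-contraction formulas assume nonnegative
    activation.
    """
    x = np.asarray(raw_emg, dtype=float)
    if x.ndim != 1:
        raise ValueError("raw_emg must be one-dimensional")
    if rate_hz <= 2.0 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff frequency")
    padlen = 3 * order
    if x.size < 3 * padlen:
        raise ValueError(
            f"series of length {x.size} too short to filter (need >= {3 * padlen})"
        )
    b, a = butter(order, cutoff_hz, btype="low", fs=rate_hz)
    rectified = np.abs(x - x.mean())
    env = filtfilt(b, a, rectified, padtype="even", padlen=padlen)
    return np.clip(env, 0.0, None)


def envelope_trial(
    raw: RawTrial, cutoff_hz: float = 6.0, order: int = 2
) -> EnvelopeTrial:
    """Apply :func:`linear_envelope` to every EMG channel of a raw trial."""
    envs = {m: linear_envelope(raw.emg[m], raw.emg_rate_hz, cutoff_hz, order) for m in raw.emg}
    return EnvelopeTrial(
        trial_id=raw.trial_id,
        participant_id=raw.participant_id,
        limb=raw.limb,
        population=raw.population,
        environment=raw.environment,
        speed=raw.speed,
        envelopes=envs,
        rate_hz=raw.emg_rate_hz,
    )


def dynamic_normalize(trials: Sequence[EnvelopeTrial]) -> list[EnvelopeTrial]:
    """Normalize all trials of one limb by the Dry-Fast envelope maxima.

    The input must be the complete trial set of a single (participant, limb)
    pair and contain exactly one Dry Fast trial. Each muscle of each trial
    is divided by that muscle's envelope maximum in the Dry Fast trial, so
    the Dry Fast trial's own maxima become exactly 1. Reference maxima are
    taken from the filtered envelope, per muscle, per limb.
    """
    if not trials:
        raise ValueError("no trials to normalize")
    keys = {(t.participant_id, t.limb) for t in trials}
    if len(keys) != 1:
        raise ValueError(f"trials span multiple limbs: {sorted(keys)}")
    refs = [t for t in trials if t.environment == "Dry" and t.speed == "Fast"]
    if len(refs) != 1:
        raise MissingReferenceTrialError(
            f"expected exactly one Dry Fast trial for {keys.pop()}, found {len(refs)}"
        )
    ref = refs[0]
    factors: dict[str, float] = {}
    for m in ref.envelopes:
        peak = float(np.max(ref.envelopes[m]))
        if peak <= 0.0:
            raise DeadChannelError(f"zero reference maximum for muscle {m}")
        factors[m] = peak
    return [
        replace(
            t,
            envelopes={m: np.asarray(t.envelopes[m]) / factors[m] for m in t.envelopes},
            normalization_factor=dict(factors),
        )
        for t in trials
    ]


__all__ = [
    "EnvelopeTrial",
    "MissingReferenceTrialError",
    "DeadChannelError",
    "linear_envelope",
    "envelope_trial",
    "dynamic_normalize",
    "MUSCLES",
]
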