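"""Gait-event detection, stride definition and time normalization.

Initial contacts are the largest vertical-acceleration peaks of the foot
IMU. Strides run from one initial contact to the next of the same foot
(left-closed, right-open in sample indexing). Stride-time outliers — any
stride whose duration deviates from the trial mean by more than three sample
standard deviations — are removed in a single pass. Retained strides are
linearly interpolated onto a fixed 101-point gait-phase grid (0..100% of
stride, endpoints included) so that muscle-pair waveforms are comparable
across strides and participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .emg import EnvelopeTrial

PHASE_GRID = np.linspace(0.0, 100.0, 101)

#: muscle pairings analysed, as (muscle_1, muscle_2)
PAIRINGS: dict[str, tuple[str, str]] = {
    "RF/ST": ("RF", "ST"),
    "TA/MG": ("TA", "MG"),
}

#: designated antagonist of each pairing
DEFAULT_ANTAGONIST: dict[str, str] = {"RF/ST": "RF", "TA/MG": "TA"}


class UnsegmentableTrialError(ValueError):
    """Fewer than two initial-contact peaks could be found."""


@dataclass(frozen=True)
class StrideSet:
    """Initial contacts, stride durations and outlier bookkeeping."""

    initial_contact_times_s: np.ndarray
    stride_durations_s: np.ndarray
    outlier_flags: np.ndarray
    retained_stride_indices: np.ndarray

    def __post_init__(self) -> None:
        ics = np.asarray(self.initial_contact_times_s)
        durs = np.asarray(self.stride_durations_s)
        if len(durs) != len(ics) - 1:
            raise ValueError("stride count must be one less than contact count")
        if np.any(durs <= 0):
            raise ValueError("stride durations must be positive")

    @property
    def n_retained(self) -> int:
        return len(self.retained_stride_indices)


@dataclass(frozen=True)
class StrideMatrix:
    """Per-stride 101-point envelopes for the two muscles of a pairing."""

    pairing: str
    muscles: tuple[str, str]
    muscle_1: np.ndarray  # (n_strides, 101)
    muscle_2: np.ndarray  # (n_strides, 101)
    stride_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.muscle_1.shape != self.muscle_2.shape:
            raise ValueError("muscle matrices must share shape")
        if self.muscle_1.ndim != 2 or self.muscle_1.shape[1] != len(PHASE_GRID):
            raise ValueError("stride rows must have 101 phase points")
        if np.any(self.muscle_1 < 0) or np.any(self.muscle_2 < 0):
            raise ValueError("envelope values must be nonnegative")

    @property
    def phase_grid(self) -> np.ndarray:
        return PHASE_GRID


def detect_initial_contacts(
    accel: np.ndarray,
    rate_hz: float,
    expected_stride_s: float,
    min_separation_frac: float = 0.5,
    rel_height_frac: float = 0.5,
) -> np.ndarray:
    """Initial-contact times from foot vertical acceleration.

    Candidate peaks must clear a prominence of twice the robust noise scale
    (median absolute deviation x 1.4826 — scale-free and insensitive to
    drift) and be separated by at least ``min_separation_frac`` of the
    expected stride time. Because initial contacts are the *greatest*
    acceleration peaks, candidates below ``rel_height_frac`` of the tallest
    candidate (measured above the signal median) are then discarded; this
    rejects noise bumps that clear the prominence floor midway between
    contacts. Raises :class:`UnsegmentableTrialError` when fewer than two
    peaks survive.
    """
    a = np.asarray(accel, dtype=float)
    if rate_hz <= 0 or expected_stride_s <= 0:
        raise ValueError("rate and expected stride time must be positive")
    mad = float(np.median(np.abs(a - np.median(a)))) * 1.4826
    prominence = 2.0 * mad if mad > 0 else None
    distance = max(1, int(round(min_separation_frac * expected_stride_s * rate_hz)))
    peaks, _ = find_peaks(a, prominence=prominence, distance=distance)
    if len(peaks) >= 1:
        baseline = float(np.median(a))
        heights = a[peaks] - baseline
        peaks = peaks[heights >= rel_height_frac * heights.max()]
    if len(peaks) < 2:
        raise UnsegmentableTrialError(
            f"found {len(peaks)} acceleration peaks; need at least 2"
        )
    return peaks / rate_hz


def estimate_stride_time(accel: np.ndarray, rate_hz: float) -> float:
    """Median interval between dominant peaks, for seeding detection.

    Uses a prominence of half the signal's range above its median so that
    only initial-contact-scale peaks contribute to the estimate.
    """
    a = np.asarray(accel, dtype=float)
    span = float(a.max() - np.median(a))
    if span <= 0:
        raise UnsegmentableTrialError("cannot estimate stride time: flat signal")
    peaks, _ = find_peaks(a, prominence=0.5 * span)
    if len(peaks) < 2:
        raise UnsegmentableTrialError("cannot estimate stride time: fewer than 2 peaks")
    return float(np.median(np.diff(peaks))) / rate_hz


def flag_stride_outliers(durations: np.ndarray) -> np.ndarray:
    """Flag strides whose duration deviates > 3 sample SDs from the mean.

    A single, non-iterative pass with the n-1 standard deviation. All-equal
    durations (SD = 0) produce no flags.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 3:
        raise ValueError(f"need at least 3 strides, got {d.size}")
    sd = d.std(ddof=1)
    if sd == 0:
        return np.zeros(d.size, dtype=bool)
    return np.abs(d - d.mean()) > 3.0 * sd


def make_stride_set(ic_times: np.ndarray) -> StrideSet:
    """Build a :class:`StrideSet` from initial-contact times."""
    ics = np.asarray(ic_times, dtype=float)
    durations = np.diff(ics)
    flags = flag_stride_outliers(durations)
    retained = np.flatnonzero(~flags)
    return StrideSet(
        initial_contact_times_s=ics,
        stride_durations_s=durations,
        outlier_flags=flags,
        retained_stride_indices=retained,
    )


def build_stride_matrix(
    envelope_trial: EnvelopeTrial, stride_set: StrideSet, pairing: str
) -> StrideMatrix:
    """Interpolate each retained stride onto the 101-point phase grid.

    Strides whose window extends past the recording are dropped rather than
    padded. Rows are ordered by stride onset time.
    """
    if pairing not in PAIRINGS:
        raise ValueError(f"unknown pairing {pairing!r}; expected one of {list(PAIRINGS)}")
    if stride_set.n_retained < 1:
        raise ValueError("no retained strides")
    m1_name, m2_name = PAIRINGS[pairing]
    rate = envelope_trial.rate_hz
    n_samples = len(envelope_trial.envelopes[m1_name])
    t_samples = np.arange(n_samples) / rate
    t_last = t_samples[-1]
    ics = stride_set.initial_contact_times_s

    rows_1, rows_2, kept_ids = [], [], []
    for i in stride_set.retained_stride_indices:
        t0, t1 = ics[i], ics[i + 1]
        if t0 < 0 or t1 > t_last:
            continue  # partially outside the recording: drop, do not pad
        grid_t = np.linspace(t0, t1, len(PHASE_GRID))
        rows_1.append(np.interp(grid_t, t_samples, envelope_trial.envelopes[m1_name]))
        rows_2.append(np.interp(grid_t, t_samples, envelope_trial.envelopes[m2_name]))
        kept_ids.append(int(i))
    if not rows_1:
        raise ValueError("every retained stride window exceeds the recording")
    return StrideMatrix(
        pairing=pairing,
        muscles=(m1_name, m2_name),
        muscle_1=np.vstack(rows_1),
        muscle_2=np.vstack(rows_2),
        stride_ids=np.asarray(kept_ids),
    )
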