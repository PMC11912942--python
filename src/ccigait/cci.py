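"""Co-contraction indices for an agonist-antagonist muscle pair.

Three established formulas, each evaluated on 101-point stride-normalized
linear envelopes and averaged over strides to one value per trial:

* **Unnithan** — the common area between the two activation waveforms: the
  integral over the gait cycle (percent phase axis, 0-100) of the pointwise
  minimum. Captures both intensity and duration of co-contraction; symmetric
  in the two muscles.
* **Rudolph** — at every phase point, (smaller/larger) * (smaller + larger),
  averaged over the 101 points. Weights simultaneous timing by total
  activation magnitude.
* **Falconer & Winter** — at every phase point, 2 * antagonist / total * 100%,
  averaged; the share of total activation attributable to the designated
  antagonist (RF for RF/ST, TA for TA/MG). Bounded in [0, 200]%.

Unnithan and Rudolph scale linearly with a common rescaling of both
envelopes; Falconer & Winter is scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import DEFAULT_ANTAGONIST, PAIRINGS, PHASE_GRID, StrideMatrix

METHODS: tuple[str, ...] = ("unnithan", "rudolph", "fw")


@dataclass(frozen=True)
class MusclePairSeries:
    """One stride's activation of a muscle pair on the 101-point phase grid."""

    emg_1: np.ndarray
    emg_2: np.ndarray
    antagonist_index: int = 0  # which of emg_1/emg_2 is the antagonist
    phase_grid: np.ndarray = field(default_factory=lambda: PHASE_GRID.copy())

    def __post_init__(self) -> None:
        e1, e2 = np.asarray(self.emg_1), np.asarray(self.emg_2)
        if e1.shape != e2.shape or e1.shape != self.phase_grid.shape:
            raise ValueError("series and phase grid must share shape")
        if np.any(e1 < 0) or np.any(e2 < 0):
            raise ValueError("activations must be nonnegative")
        if self.antagonist_index not in (0, 1):
            raise ValueError("antagonist_index must be 0 or 1")

    @property
    def emg_small(self) -> np.ndarray:
        return np.minimum(self.emg_1, self.emg_2)

    @property
    def emg_large(self) -> np.ndarray:
        return np.maximum(self.emg_1, self.emg_2)

    @property
    def emg_total(self) -> np.ndarray:
        return np.asarray(self.emg_1) + np.asarray(self.emg_2)

    @property
    def emg_antagonist(self) -> np.ndarray:
        return self.emg_1 if self.antagonist_index == 0 else self.emg_2


def _as_arrays(emg_1, emg_2) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.asarray(emg_1, dtype=float)
    e2 = np.asarray(emg_2, dtype=float)
    if e1.shape != e2.shape or e1.ndim != 1:
        raise ValueError("the two series must be 1-D with equal length")
    if np.any(e1 < 0) or np.any(e2 < 0):
        raise ValueError("activations must be nonnegative")
    return e1, e2


def cci_unnithan(emg_1: np.ndarray, emg_2: np.ndarray) -> float:
    """Common-area CCI: trapezoidal integral of min(emg_1, emg_2) over 0-100% stride.

    Units: normalized activation x percent stride. Symmetric in argument order.
    """
    e1, e2 = _as_arrays(emg_1, emg_2)
    phase = np.linspace(0.0, 100.0, e1.size)
    return float(np.trapezoid(np.minimum(e1, e2), phase))


def cci_rudolph(
    emg_1: np.ndarray, emg_2: np.ndarray, zero_policy: str = "zero"
) -> float:
    """Rudolph CCI: mean over phase of (EMG_s / EMG_l) * (EMG_s + EMG_l).

    Phase points where the larger activation is zero carry no co-contraction;
    with ``zero_policy="zero"`` (default) they contribute 0 to the mean, with
    ``"drop"`` they are excluded from it.
    """
    e1, e2 = _as_arrays(emg_1, emg_2)
    small, large = np.minimum(e1, e2), np.maximum(e1, e2)
    active = large > 0
    values = np.zeros_like(large)
    np.divide(small, large, out=values, where=active)
    values *= small + large
    if zero_policy == "zero":
        return float(values.mean())
    if zero_policy == "drop":
        return float(values[active].mean()) if active.any() else 0.0
    raise ValueError(f"unknown zero_policy {zero_policy!r}")


def cci_falconer_winter(
    emg_antagonist: np.ndarray, emg_agonist: np.ndarray, zero_policy: str = "zero"
) -> float:
    """Falconer & Winter CCI: mean over phase of 2 * EMG_ant / EMG_total * 100%.

    Bounded in [0, 200]. Phase points with zero total activation contribute 0
    (``zero_policy="zero"``) or are dropped (``"drop"``).
    """
    ant, ago = _as_arrays(emg_antagonist, emg_agonist)
    total = ant + ago
    active = total > 0
    values = np.zeros_like(total)
    np.divide(2.0 * ant, total, out=values, where=active)
    values *= 100.0
    if zero_policy == "zero":
        return float(values.mean())
    if zero_policy == "drop":
        return float(values[active].mean()) if active.any() else 0.0
    raise ValueError(f"unknown zero_policy {zero_policy!r}")


@dataclass(frozen=True)
class TrialCCI:
    """Per-stride CCI values of one trial and their mean."""

    pairing: str
    method: str
    antagonist: str
    per_stride: np.ndarray
    n_strides: int

    @property
    def trial_value(self) -> float:
        return float(np.mean(self.per_stride))


def cci_trial(
    stride_matrix: StrideMatrix,
    method: str,
    antagonist: str | None = None,
    zero_policy: str = "zero",
) -> TrialCCI:
    """Apply one CCI formula to every retained stride and average.

    ``antagonist`` defaults to the pairing's designated antagonist (RF for
    RF/ST, TA for TA/MG) and is only consulted by the Falconer & Winter
    formula.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if stride_matrix.muscle_1.shape[0] < 1:
        raise ValueError("empty stride matrix")
    if antagonist is None:
        antagonist = DEFAULT_ANTAGONIST[stride_matrix.pairing]
    if antagonist not in stride_matrix.muscles:
        raise ValueError(
            f"antagonist {antagonist!r} is not in pairing {stride_matrix.pairing}"
        )
    ant_first = stride_matrix.muscles[0] == antagonist

    values = []
    for row_1, row_2 in zip(stride_matrix.muscle_1, stride_matrix.muscle_2):
        if method == "unnithan":
            values.append(cci_unnithan(row_1, row_2))
        elif method == "rudolph":
            values.append(cci_rudolph(row_1, row_2, zero_policy))
        else:
            ant_row, ago_row = (row_1, row_2) if ant_first else (row_2, row_1)
            values.append(cci_falconer_winter(ant_row, ago_row, zero_policy))
    return TrialCCI(
        pairing=stride_matrix.pairing,
        method=method,
        antagonist=antagonist,
        per_stride=np.asarray(values),
        n_strides=len(values),
    )


__all__ = [
    "METHODS",
    "PAIRINGS",
    "DEFAULT_ANTAGONIST",
    "MusclePairSeries",
    "TrialCCI",
    "cci_unnithan",
    "cci_rudolph",
    "cci_falconer_winter",
    "cci_trial",
]
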