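"""Long-format CSV readers and writers for every pipeline stage.

Signal streams use one tidy table with columns
``trial_id,participant_id,limb,population,environment,speed,stream,channel,
time_s,value`` where ``stream`` is ``emg``, ``accel`` or ``envelope``.
A cohort directory additionally holds ``metadata.csv`` (one row per trial,
with sampling rates) and, for simulated cohorts, ``ground_truth_ics.csv``
with the true initial-contact times. Stride tables and CCI tables are plain
wide CSVs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .emg import EnvelopeTrial
from .segmentation import StrideSet
from .synthetic import MUSCLES, RawTrial, SimulationConfig

META_COLUMNS = [
    "trial_id",
    "participant_id",
    "limb",
    "population",
    "environment",
    "speed",
    "emg_rate_hz",
    "imu_rate_hz",
]


def load_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from YAML (keys = field names)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("burst_centers", "burst_widths", "burst_amplitudes"):
        if key in data:
            data[key] = {m: tuple(v) for m, v in data[key].items()}
    if "limbs" in data:
        data["limbs"] = tuple(data["limbs"])
    return SimulationConfig(**data)


def _signal_frame(trial, stream: str, channels: Mapping[str, np.ndarray], rate: float) -> pd.DataFrame:
    frames = []
    for channel, values in channels.items():
        values = np.asarray(values)
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": trial.trial_id,
                    "participant_id": trial.participant_id,
                    "limb": trial.limb,
                    "population": trial.population,
                    "environment": trial.environment,
                    "speed": trial.speed,
                    "stream": stream,
                    "channel": channel,
                    "time_s": np.arange(values.size) / rate,
                    "value": values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_cohort(trials: Sequence[RawTrial], out_dir: str | Path) -> None:
    """Write raw signals, metadata and ground-truth initial contacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    signal_frames, meta_rows, truth_rows = [], [], []
    for t in trials:
        signal_frames.append(_signal_frame(t, "emg", t.emg, t.emg_rate_hz))
        signal_frames.append(
            _signal_frame(t, "accel", {"vertical": t.accel_vertical}, t.imu_rate_hz)
        )
        meta_rows.append(
            {
                "trial_id": t.trial_id,
                "participant_id": t.participant_id,
                "limb": t.limb,
                "population": t.population,
                "environment": t.environment,
                "speed": t.speed,
                "emg_rate_hz": t.emg_rate_hz,
                "imu_rate_hz": t.imu_rate_hz,
            }
        )
        for i, ic in enumerate(t.true_initial_contacts_s):
            truth_rows.append({"trial_id": t.trial_id, "ic_index": i, "time_s": ic})
    pd.concat(signal_frames, ignore_index=True).to_csv(out / "signals.csv", index=False)
    pd.DataFrame(meta_rows, columns=META_COLUMNS).to_csv(out / "metadata.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth_ics.csv", index=False)


def read_cohort(in_dir: str | Path) -> list[RawTrial]:
    """Read raw trials back from a cohort directory."""
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "metadata.csv")
    signals = pd.read_csv(in_dir / "signals.csv")
    truth_path = in_dir / "ground_truth_ics.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    trials = []
    for _, row in meta.iterrows():
        sub = signals[signals["trial_id"] == row["trial_id"]]
        emg = {
            m: sub[(sub["stream"] == "emg") & (sub["channel"] == m)]["value"].to_numpy()
            for m in MUSCLES
        }
        accel = sub[(sub["stream"] == "accel") & (sub["channel"] == "vertical")][
            "value"
        ].to_numpy()
        if truth is not None:
            ics = truth[truth["trial_id"] == row["trial_id"]].sort_values("ic_index")[
                "time_s"
            ].to_numpy()
        else:
            ics = np.array([])
        trials.append(
            RawTrial(
                trial_id=row["trial_id"],
                participant_id=row["participant_id"],
                limb=row["limb"],
                population=row["population"],
                environment=row["environment"],
                speed=row["speed"],
                emg=emg,
                accel_vertical=accel,
                emg_rate_hz=float(row["emg_rate_hz"]),
                imu_rate_hz=float(row["imu_rate_hz"]),
                true_initial_contacts_s=ics,
            )
        )
    return trials


def write_envelopes(env_trials: Sequence[EnvelopeTrial], out_dir: str | Path) -> None:
    """Write normalized envelopes (stream=envelope) plus normalization factors."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames, factor_rows = [], []
    for t in env_trials:
        frames.append(_signal_frame(t, "envelope", t.envelopes, t.rate_hz))
        if t.normalization_factor:
            for m, f in t.normalization_factor.items():
                factor_rows.append(
                    {
                        "participant_id": t.participant_id,
                        "limb": t.limb,
                        "trial_id": t.trial_id,
                        "muscle": m,
                        "normalization_factor": f,
                    }
                )
    pd.concat(frames, ignore_index=True).to_csv(out / "envelopes.csv", index=False)
    if factor_rows:
        pd.DataFrame(factor_rows).to_csv(out / "normalization_factors.csv", index=False)


def read_envelopes(in_dir: str | Path, metadata_dir: str | Path | None = None) -> list[EnvelopeTrial]:
    """Read envelope trials from ``envelopes.csv`` (+ metadata for rates)."""
    in_dir = Path(in_dir)
    signals = pd.read_csv(in_dir / "envelopes.csv")
    meta = pd.read_csv(Path(metadata_dir or in_dir) / "metadata.csv")
    factors_path = in_dir / "normalization_factors.csv"
    factors = pd.read_csv(factors_path) if factors_path.exists() else None
    trials = []
    for _, row in meta.iterrows():
        sub = signals[signals["trial_id"] == row["trial_id"]]
        envs = {
            m: sub[sub["channel"] == m]["value"].to_numpy() for m in MUSCLES
        }
        norm = None
        if factors is not None:
            fsub = factors[factors["trial_id"] == row["trial_id"]]
            if len(fsub):
                norm = dict(zip(fsub["muscle"], fsub["normalization_factor"]))
        trials.append(
            EnvelopeTrial(
                trial_id=row["trial_id"],
                participant_id=row["participant_id"],
                limb=row["limb"],
                population=row["population"],
                environment=row["environment"],
                speed=row["speed"],
                envelopes=envs,
                rate_hz=float(row["emg_rate_hz"]),
                normalization_factor=norm,
            )
        )
    return trials


def write_stride_tables(
    stride_sets: Mapping[str, StrideSet], path: str | Path
) -> None:
    """Write per-trial stride windows and outlier flags to one CSV."""
    rows = []
    for trial_id, ss in stride_sets.items():
        ics = ss.initial_contact_times_s
        for i, dur in enumerate(ss.stride_durations_s):
            rows.append(
                {
                    "trial_id": trial_id,
                    "stride_id": i,
                    "t_start_s": ics[i],
                    "t_end_s": ics[i + 1],
                    "duration_s": dur,
                    "outlier": bool(ss.outlier_flags[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stride_tables(path: str | Path) -> dict[str, StrideSet]:
    """Inverse of :func:`write_stride_tables`."""
    df = pd.read_csv(path)
    out: dict[str, StrideSet] = {}
    for trial_id, sub in df.groupby("trial_id"):
        sub = sub.sort_values("stride_id")
        ics = np.concatenate([sub["t_start_s"].to_numpy(), [sub["t_end_s"].iloc[-1]]])
        flags = sub["outlier"].to_numpy(dtype=bool)
        out[str(trial_id)] = StrideSet(
            initial_contact_times_s=ics,
            stride_durations_s=np.diff(ics),
            outlier_flags=flags,
            retained_stride_indices=np.flatnonzero(~flags),
        )
    return out
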