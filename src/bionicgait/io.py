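"""CSV + JSON-sidecar persistence for trials, fascicle traces, metric
tables and cohort tables.

CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory header row;
units and acquisition metadata live in a JSON sidecar next to each CSV
(same stem, ``.json`` suffix) so files round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emg import EmgRecording
from .gait import GRID
from .spindle import CYCLE_GRID, FascicleTrace
from .synth import ArchetypeSpec, SyntheticTrial

__all__ = [
    "write_trial", "read_trial",
    "write_emg", "read_emg",
    "write_fascicles", "read_fascicles",
    "write_metrics", "read_metrics",
    "write_cohort", "read_cohort",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_emg(rec: EmgRecording, path) -> None:
    path = Path(path)
    n = rec.n_samples
    df = pd.DataFrame({"time_s": np.arange(n) / rec.sample_rate})
    for name, x in rec.channels.items():
        df[name] = x
    df.to_csv(path, index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump({"sample_rate_hz": rec.sample_rate,
                   "units": "arbitrary", "kind": "emg"}, fh, indent=2)


def read_emg(path) -> EmgRecording:
    path = Path(path)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path)
    channels = {c: df[c].to_numpy() for c in df.columns if c != "time_s"}
    return EmgRecording(meta["sample_rate_hz"], channels)


def write_fascicles(traces: dict[str, FascicleTrace], path) -> None:
    path = Path(path)
    df = pd.DataFrame({"cycle_pct": CYCLE_GRID})
    for m, tr in traces.items():
        df[f"strain_{m}"] = tr.strain
    df.to_csv(path, index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump({"units": "dimensionless (positive = lengthening)",
                   "n_cycles": {m: tr.n_cycles for m, tr in traces.items()},
                   "kind": "fascicle"}, fh, indent=2)


def read_fascicles(path) -> dict[str, FascicleTrace]:
    path = Path(path)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path)
    out = {}
    for c in df.columns:
        if c.startswith("strain_"):
            m = c[len("strain_"):]
            out[m] = FascicleTrace(df[c].to_numpy(), m,
                                   meta.get("n_cycles", {}).get(m, 1))
    return out


def write_trial(trial: SyntheticTrial, path) -> None:
    """One trial as a cycle-grid CSV plus a metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"cycle_pct": GRID,
                       "angle_deg": trial.angle,
                       "torque_nm_per_kg": trial.torque})
    for side, kin in (("ipsi", trial.kinematics_ipsi),
                      ("contra", trial.kinematics_contra)):
        for j, x in kin.items():
            df[f"{side}_{j}_deg"] = x
    df.to_csv(path, index=False)
    meta = {
        "kind": "gait_trial",
        "condition": trial.condition,
        "speed_m_per_s": trial.speed,
        "stance_end_pct": trial.stance_end_pct,
        "cycle_duration_s": trial.cycle_duration_s,
        "body_mass_kg": trial.body_mass,
        "units": {"angle": "deg (DF positive)", "torque": "Nm/kg"},
    }
    if trial.spec is not None:
        meta["spec"] = {
            "group_label": trial.spec.group_label,
            "afferent_level": trial.spec.afferent_level,
            "gait_biomimeticness": trial.spec.gait_biomimeticness,
            "noise_sd": trial.spec.noise_sd,
            "seed": trial.spec.seed,
        }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_trial(path) -> SyntheticTrial:
    path = Path(path)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path)
    kin_i, kin_c = {}, {}
    for c in df.columns:
        if c.startswith("ipsi_"):
            kin_i[c[len("ipsi_"):-len("_deg")]] = df[c].to_numpy()
        elif c.startswith("contra_"):
            kin_c[c[len("contra_"):-len("_deg")]] = df[c].to_numpy()
    spec = None
    if "spec" in meta:
        spec = ArchetypeSpec(**meta["spec"])
    return SyntheticTrial(
        meta["condition"], meta["speed_m_per_s"],
        df["angle_deg"].to_numpy(), df["torque_nm_per_kg"].to_numpy(),
        kin_i, kin_c, {}, EmgRecording(2000.0, {}),
        meta["stance_end_pct"], meta["cycle_duration_s"],
        meta["body_mass_kg"], spec)


def write_metrics(df: pd.DataFrame, path) -> None:
    """Tidy metric table (subject, condition, metric, value, units)."""
    path = Path(path)
    required = {"subject", "condition", "metric", "value", "units"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metric table missing columns {sorted(missing)}")
    df.to_csv(path, index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump({"kind": "metrics", "schema": sorted(df.columns)}, fh, indent=2)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort(df: pd.DataFrame, path, units: dict | None = None) -> None:
    path = Path(path)
    if df["subject"].duplicated().any():
        raise ValueError("duplicated subject ids in cohort table")
    df.to_csv(path, index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump({"kind": "cohort", "columns": list(df.columns),
                   "units": units or {}}, fh, indent=2)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
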