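"""Delimited-table I/O for recordings, MVC series and pipeline outputs.

One limb/session is stored as three comma-separated files with header rows:

* ``kinematics.csv`` -- ``time_s, elbow_angle_deg`` (125 Hz)
* ``emg.csv``        -- ``time_s, emg_tb_v, emg_bb_v, emg_br_v`` (1000 Hz)
* ``mvc.csv``        -- ``time_s, trial, emg_bb_v, emg_br_v, torque_nm``

plus a cohort-level ``manifest.csv`` (subject, group, limb, age, declared
rates and file paths).  Simulated sessions additionally get a
``ground_truth.json`` sidecar with the planted parameters.  Readers validate
schema (missing columns are named), time monotonicity and the declared
sampling rates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EMG_CHANNELS, FLEXORS, MVCTrial, Recording, TimeSeries
from .simulate import GroundTruth, SimulatedSession

EMG_COLUMNS = {"TB": "emg_tb_v", "BB": "emg_bb_v", "BR": "emg_br_v"}


class SchemaError(ValueError):
    """A file does not match the expected table schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_clock(df: pd.DataFrame, path, expected_fs: float | None) -> float:
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise SchemaError(f"{path}: time_s must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    if expected_fs is not None:
        if abs(fs - expected_fs) / expected_fs > 0.01:
            raise SchemaError(f"{path}: sampling rate {fs:.1f} Hz != declared {expected_fs} Hz")
        return float(expected_fs)  # trust the validated declaration exactly
    return fs


def write_session(directory, session: SimulatedSession) -> dict:
    """Write one simulated session's tables; returns its manifest row."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rec = session.recording
    kin = d / "kinematics.csv"
    pd.DataFrame(
        {"time_s": rec.angle.times(), "elbow_angle_deg": rec.angle.samples}
    ).to_csv(kin, index=False)
    emg = d / "emg.csv"
    pd.DataFrame(
        {"time_s": rec.emg["TB"].times()}
        | {EMG_COLUMNS[ch]: rec.emg[ch].samples for ch in EMG_CHANNELS}
    ).to_csv(emg, index=False)
    mvc = d / "mvc.csv"
    frames = []
    for t in session.mvc_trials:
        frames.append(
            pd.DataFrame(
                {"time_s": t.torque.times(), "trial": t.trial_id}
                | {EMG_COLUMNS[ch]: t.emg[ch].samples for ch in FLEXORS}
                | {"torque_nm": t.torque.samples}
            )
        )
    pd.concat(frames).to_csv(mvc, index=False)
    if session.truth is not None:
        truth = dataclasses.asdict(session.truth)
        truth["events"] = [dataclasses.asdict(e) for e in session.truth.events]
        (d / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return dict(
        subject=rec.subject, group=rec.group, limb=rec.limb, age=rec.age,
        fs_emg=rec.fs_emg, fs_kin=rec.fs_kin,
        kinematics=str(kin), emg=str(emg), mvc=str(mvc),
    )


def read_recording(row: dict) -> Recording:
    """Load a Recording from a manifest row (validating schema and rates)."""
    kin = pd.read_csv(row["kinematics"], float_precision="round_trip")
    _require_columns(kin, ["time_s", "elbow_angle_deg"], row["kinematics"])
    fs_kin = _check_clock(kin, row["kinematics"], row.get("fs_kin"))
    emg = pd.read_csv(row["emg"], float_precision="round_trip")
    _require_columns(emg, ["time_s"] + list(EMG_COLUMNS.values()), row["emg"])
    fs_emg = _check_clock(emg, row["emg"], row.get("fs_emg"))
    t0_kin = float(kin["time_s"].iloc[0])
    t0_emg = float(emg["time_s"].iloc[0])
    return Recording(
        subject=str(row["subject"]),
        group=str(row["group"]),
        limb=str(row["limb"]),
        age=float(row.get("age", np.nan)),
        emg={
            ch: TimeSeries(emg[col].to_numpy(), fs_emg, label=ch, t0=t0_emg)
            for ch, col in EMG_COLUMNS.items()
        },
        angle=TimeSeries(kin["elbow_angle_deg"].to_numpy(), fs_kin, "elbow_angle", t0_kin),
    )


def read_mvc(path) -> list[MVCTrial]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s", "trial", "emg_bb_v", "emg_br_v", "torque_nm"], path)
    trials = []
    for tid, g in df.groupby("trial"):
        fs = _check_clock(g, path, None)
        t0 = float(g["time_s"].iloc[0])
        trials.append(
            MVCTrial(
                emg={ch: TimeSeries(g[EMG_COLUMNS[ch]].to_numpy(), fs, ch, t0) for ch in FLEXORS},
                torque=TimeSeries(g["torque_nm"].to_numpy(), fs, "torque", t0),
                trial_id=int(tid),
            )
        )
    return trials


def read_ground_truth(directory) -> GroundTruth | None:
    p = Path(directory) / "ground_truth.json"
    if not p.exists():
        return None
    raw = json.loads(p.read_text())
    from .core import MovementBounds

    raw["events"] = [MovementBounds(**e) for e in raw["events"]]
    return GroundTruth(**raw)


def write_manifest(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path) -> list[dict]:
    df = pd.read_csv(path)
    _require_columns(df, ["subject", "group", "limb", "kinematics", "emg", "mvc"], path)
    return df.to_dict("records")
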