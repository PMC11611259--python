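"""CSV/JSON round-tripping for time series and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .observer import PerceptionTrace
from .paradigms import CurrentWaveform, MotionProfile

__all__ = [
    "read_current_csv",
    "write_current_csv",
    "read_motion_csv",
    "write_motion_csv",
    "write_perception_csv",
    "write_json",
]

MOTION_COLUMNS = ["t_s", "omega_x_dps", "omega_y_dps", "omega_z_dps", "a_x_mps2", "a_y_mps2", "a_z_mps2"]


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")


def read_current_csv(path) -> CurrentWaveform:
    """Read a GVS current waveform from a CSV with columns ``t_s, current_mA``."""
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "current_mA"], path)
    bad = df.index[df[["t_s", "current_mA"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-numeric or missing values at row(s) {list(bad[:5])}")
    return CurrentWaveform(time=df["t_s"].to_numpy(), current_ma=df["current_mA"].to_numpy())


def write_current_csv(path, waveform: CurrentWaveform) -> None:
    pd.DataFrame({"t_s": waveform.time, "current_mA": waveform.current_ma}).to_csv(path, index=False)


def read_motion_csv(path) -> MotionProfile:
    """Read a 6DoF motion profile (angular velocity + linear acceleration)."""
    df = pd.read_csv(path)
    _require_columns(df, MOTION_COLUMNS, path)
    bad = df.index[df[MOTION_COLUMNS].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-numeric or missing values at row(s) {list(bad[:5])}")
    t = df["t_s"].to_numpy()
    dt = float(t[1] - t[0])
    omega = df[["omega_x_dps", "omega_y_dps", "omega_z_dps"]].to_numpy()
    accel = df[["a_x_mps2", "a_y_mps2", "a_z_mps2"]].to_numpy()
    angles = np.cumsum(omega, axis=0) * dt  # single-axis readout; exact for planar profiles
    return MotionProfile(
        time=t,
        roll_deg=angles[:, 0],
        pitch_deg=-angles[:, 1],
        yaw_deg=angles[:, 2],
        omega_dps=omega,
        accel_mps2=accel,
        label=str(path),
    )


def write_motion_csv(path, motion: MotionProfile) -> None:
    df = pd.DataFrame(
        {
            "t_s": motion.time,
            "omega_x_dps": motion.omega_dps[:, 0],
            "omega_y_dps": motion.omega_dps[:, 1],
            "omega_z_dps": motion.omega_dps[:, 2],
            "a_x_mps2": motion.accel_mps2[:, 0],
            "a_y_mps2": motion.accel_mps2[:, 1],
            "a_z_mps2": motion.accel_mps2[:, 2],
        }
    )
    df.to_csv(path, index=False)


def write_perception_csv(path, trace: PerceptionTrace) -> None:
    df = pd.DataFrame(
        {
            "t_s": trace.time,
            "roll_tilt_deg": trace.roll_tilt,
            "pitch_tilt_deg": trace.pitch_tilt,
            "omega_hat_x_dps": trace.omega_hat[:, 0],
            "omega_hat_y_dps": trace.omega_hat[:, 1],
            "omega_hat_z_dps": trace.omega_hat[:, 2],
            "g_hat_x": trace.g_hat[:, 0],
            "g_hat_y": trace.g_hat[:, 1],
            "g_hat_z": trace.g_hat[:, 2],
            "a_hat_x_mps2": trace.a_hat[:, 0],
            "a_hat_y_mps2": trace.a_hat[:, 1],
            "a_hat_z_mps2": trace.a_hat[:, 2],
        }
    )
    df.to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return super().default(obj)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")
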