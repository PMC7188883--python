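"""File formats: 200-Hz trial logs and subject-metadata sidecars.

One CSV holds the frame-level logs of one or more sessions (columns
below), a second CSV holds the per-subject metadata.  Both start with a
``#``-prefixed header block stating the format version and conventions:
display coordinates in mm with the origin at the start position, +x
rightward, +y toward the 90-degree target; clockwise-positive angles in
degrees; 1-based trial numbers; 0-based frame numbers.

Trial log columns:
    subject_id, group, block (practice|CW|CCW), trial (1..100 within the
    session), block_trial (1-based within the block), rotation_deg,
    target_angle_deg, frame, time_s, accel_x, accel_y, cursor_x_mm,
    cursor_y_mm
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialLog",
    "FORMAT_HEADER",
    "TrialLogParseError",
    "write_trial_logs",
    "read_trial_logs",
    "write_subject_meta",
    "read_subject_meta",
    "load_config",
]

FORMAT_VERSION = "1"

FORMAT_HEADER = (
    f"# tiltadapt trial-log format v{FORMAT_VERSION}\n"
    "# units: mm (display, origin at start, +x right, +y toward the 90 deg target),\n"
    "#        degrees (angles, clockwise-positive), seconds; accel dimensionless in [-1, 1]\n"
    "# trial numbers 1-based (within session and within block); frames 0-based\n"
)

REQUIRED_COLUMNS = [
    "subject_id",
    "group",
    "block",
    "trial",
    "block_trial",
    "rotation_deg",
    "target_angle_deg",
    "frame",
    "time_s",
    "accel_x",
    "accel_y",
    "cursor_x_mm",
    "cursor_y_mm",
]

META_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "MMSE",
    "UPDRS",
    "HY",
    "duration",
    "sex",
    "direction_first",
]


class TrialLogParseError(ValueError):
    """Trial-log file violates the format contract."""


@dataclass
class TrialLog:
    """One trial's 200-Hz time series plus its labels."""

    subject_id: str
    group: str
    block: str  # practice | CW | CCW
    trial: int  # 1-based within session
    block_trial: int  # 1-based within block
    rotation_deg: float
    target_angle_deg: float
    frame: np.ndarray = field(repr=False, default=None)
    time_s: np.ndarray = field(repr=False, default=None)
    accel_x: np.ndarray = field(repr=False, default=None)
    accel_y: np.ndarray = field(repr=False, default=None)
    cursor_x_mm: np.ndarray = field(repr=False, default=None)
    cursor_y_mm: np.ndarray = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return len(self.frame)


def _logs_to_frame(logs: Iterable[TrialLog]) -> pd.DataFrame:
    parts = []
    for log in logs:
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": log.subject_id,
                    "group": log.group,
                    "block": log.block,
                    "trial": log.trial,
                    "block_trial": log.block_trial,
                    "rotation_deg": log.rotation_deg,
                    "target_angle_deg": log.target_angle_deg,
                    "frame": log.frame,
                    "time_s": log.time_s,
                    "accel_x": log.accel_x,
                    "accel_y": log.accel_y,
                    "cursor_x_mm": log.cursor_x_mm,
                    "cursor_y_mm": log.cursor_y_mm,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=REQUIRED_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def write_trial_logs(logs: Iterable[TrialLog], path: str | Path) -> None:
    """Write trial logs (any number of sessions) to one CSV with header block."""
    df = _logs_to_frame(logs)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(FORMAT_HEADER)
        df.to_csv(fh, index=False, float_format="%.9g")


def read_trial_logs(path: str | Path) -> dict[str, list[TrialLog]]:
    """Read a trial-log CSV into per-subject lists of :class:`TrialLog`.

    Validates required columns, the accelerometer range and frame
    contiguity; errors name the offending row or trial.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogParseError(f"{path}: missing columns {missing}")
    if df.empty:
        return {}
    for col in ("accel_x", "accel_y"):
        bad = df.index[df[col].abs() > 1.0]
        if len(bad):
            raise TrialLogParseError(
                f"{path}: |{col}| > 1 at data row {int(bad[0])} "
                f"(value {df.loc[bad[0], col]!r})"
            )
    sessions: dict[str, list[TrialLog]] = {}
    for (subject, trial), chunk in df.groupby(["subject_id", "trial"], sort=True):
        frames = chunk["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise TrialLogParseError(
                f"{path}: non-contiguous frames for subject {subject} trial {trial}"
            )
        first = chunk.iloc[0]
        log = TrialLog(
            subject_id=str(subject),
            group=str(first["group"]),
            block=str(first["block"]),
            trial=int(trial),
            block_trial=int(first["block_trial"]),
            rotation_deg=float(first["rotation_deg"]),
            target_angle_deg=float(first["target_angle_deg"]),
            frame=frames.astype(int),
            time_s=chunk["time_s"].to_numpy(dtype=float),
            accel_x=chunk["accel_x"].to_numpy(dtype=float),
            accel_y=chunk["accel_y"].to_numpy(dtype=float),
            cursor_x_mm=chunk["cursor_x_mm"].to_numpy(dtype=float),
            cursor_y_mm=chunk["cursor_y_mm"].to_numpy(dtype=float),
        )
        sessions.setdefault(log.subject_id, []).append(log)
    for logs in sessions.values():
        logs.sort(key=lambda tl: tl.trial)
    return sessions


def write_subject_meta(meta: pd.DataFrame, path: str | Path) -> None:
    """Write the subject-metadata sidecar CSV."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns {missing}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# tiltadapt subject metadata v{FORMAT_VERSION}\n")
        meta.to_csv(fh, index=False)


def read_subject_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, comment="#")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise TrialLogParseError(f"{path}: metadata missing columns {missing}")
    if (meta["MMSE"].dropna() > 30).any() or (meta["MMSE"].dropna() < 0).any():
        raise TrialLogParseError(f"{path}: MMSE outside [0, 30]")
    return meta


def load_config(path: str | Path) -> dict:
    """Load a flat YAML configuration file into a dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
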