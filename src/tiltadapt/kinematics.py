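"""Per-trial kinematic scoring and adaptation-curve construction.

Each trial's display cursor trace is scored for movement onset (y-velocity
exceeding the trial mean + 2.5 SD), the frame of peak y-velocity, the
signed movement angle between the target line and the velocity vector at
that frame (clockwise positive), the adaptation effect ``p_t - angle``
(0 = no compensation, p_t = full compensation), movement time (onset to
peak), and the lateral trajectory error.  Trials whose effect exceeds the
rotation-shifted bound +-(c + p_t) are excluded as outliers; CW and CCW
blocks are then averaged (CCW sign-flipped) into a 40-entry per-subject
adaptation curve with single-block substitution where one side is
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateTrialError",
    "NoOnsetError",
    "ExclusionRule",
    "TrialFeatures",
    "AdaptationCurve",
    "detect_onset",
    "movement_angle_at_peak",
    "adaptation_effect",
    "trajectory_error",
    "apply_exclusion",
    "build_adaptation_curve",
    "score_trial",
    "score_session",
    "session_curve",
]

TE_MODES = ("mean_abs", "signed_mean", "mean_squared")


class DegenerateTrialError(ValueError):
    """Trial velocity series unusable (zero variance / zero velocity at peak)."""


class NoOnsetError(ValueError):
    """The onset threshold is never crossed in the trial."""


@dataclass(frozen=True)
class ExclusionRule:
    """Outlier bound: exclude if effect > c + p_t (p_t >= 0) or < -c + p_t (p_t < 0).

    The analysis is insensitive to ``bound_c`` above ~11.5 degrees; 15 is
    the default used throughout.
    """

    bound_c: float = 15.0

    def __post_init__(self) -> None:
        if self.bound_c <= 11.5:
            raise ValueError("bound_c must exceed 11.5 degrees")


@dataclass
class TrialFeatures:
    """Scored scalars for one trial (angles in degrees, times in ms)."""

    subject_id: str
    block: str
    trial: int
    block_trial: int
    rotation_deg: float
    target_angle_deg: float
    onset_frame: int | None = None
    peak_frame: int | None = None
    movement_angle_deg: float = np.nan
    adaptation_effect_deg: float = np.nan
    movement_time_ms: float = np.nan
    trajectory_error_mm: float = np.nan
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class AdaptationCurve:
    """40-entry CW/CCW-averaged adaptation curve for one subject.

    ``source`` tags each entry with which blocks contributed: ``both``,
    ``cw_only``, ``ccw_only`` (single-block substitution after an outlier)
    or ``missing`` (both blocks excluded; value is NaN).
    """

    subject_id: str
    values: np.ndarray
    source: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.source = np.asarray(self.source, dtype=object)
        if self.values.shape != (40,) or self.source.shape != (40,):
            raise ValueError("adaptation curve must have 40 entries")
        missing = self.source == "missing"
        if np.any(np.isfinite(self.values[missing])):
            raise ValueError("entries tagged missing must carry no value")


def _velocity(pos: np.ndarray, time_s: np.ndarray) -> np.ndarray:
    return np.gradient(np.asarray(pos, dtype=float), np.asarray(time_s, dtype=float))


def detect_onset(vy: Sequence[float] | np.ndarray) -> int:
    """First frame where y-velocity exceeds the trial mean + 2.5 SD.

    Mean and SD are taken over the whole trial's y-velocity series (the
    log contract carries no separate pre-go baseline).  Raises
    :class:`DegenerateTrialError` for a zero-variance series and
    :class:`NoOnsetError` when the threshold is never crossed.
    """
    v = np.asarray(vy, dtype=float)
    if v.size < 2:
        raise DegenerateTrialError("velocity series too short")
    sd = float(np.std(v))
    if sd == 0.0:
        raise DegenerateTrialError("zero-variance velocity series")
    threshold = float(np.mean(v)) + 2.5 * sd
    above = np.nonzero(v > threshold)[0]
    if above.size == 0:
        raise NoOnsetError("onset threshold never crossed")
    return int(above[0])


def _signed_angle_cw(target_angle_deg: float, vx: float, vy: float) -> float:
    """Clockwise-positive angle between the target direction and (vx, vy)."""
    th = np.radians(target_angle_deg)
    ux, uy = np.cos(th), np.sin(th)
    if vx == 0.0 and vy == 0.0:
        raise DegenerateTrialError("zero velocity vector at peak")
    ccw = np.arctan2(ux * vy - uy * vx, ux * vx + uy * vy)
    return float(-np.degrees(ccw))


def movement_angle_at_peak(log, onset: int) -> tuple[int, float]:
    """Frame of peak display y-velocity (>= onset) and the movement angle there.

    The movement angle is the signed (clockwise-positive) angle between
    the straight line to the target and the cursor velocity vector at the
    peak frame.
    """
    vy = _velocity(log.cursor_y_mm, log.time_s)
    vx = _velocity(log.cursor_x_mm, log.time_s)
    if not (0 <= onset < len(vy)):
        raise ValueError("onset outside the trial")
    peak = onset + int(np.argmax(vy[onset:]))
    angle = _signed_angle_cw(log.target_angle_deg, float(vx[peak]), float(vy[peak]))
    return peak, angle


def adaptation_effect(movement_angle_deg: float, rotation_deg: float) -> float:
    """Compensatory angle ``p_t - movement_angle``.

    Zero for an unadapted straight reach under rotation p_t, and p_t for
    full compensation, so adaptation curves rise from 0 toward the
    schedule.
    """
    return rotation_deg - movement_angle_deg


def trajectory_error(log, onset: int = 0, mode: str = "mean_abs") -> float:
    """Average lateral deviation of the cursor path from the start x, in mm.

    ``mean_abs`` (default) averages |x - x0|; ``signed_mean`` averages the
    raw deviation; ``mean_squared`` averages its square (mm^2).
    """
    if mode not in TE_MODES:
        raise ValueError(f"mode must be one of {TE_MODES}")
    x = np.asarray(log.cursor_x_mm, dtype=float)
    dx = x[onset:] - x[0]
    if dx.size < 1:
        raise ValueError("empty frame window for trajectory error")
    if mode == "mean_abs":
        return float(np.mean(np.abs(dx)))
    if mode == "signed_mean":
        return float(np.mean(dx))
    return float(np.mean(dx**2))


def apply_exclusion(
    effects: Sequence[float] | np.ndarray,
    rotations: Sequence[float] | np.ndarray,
    rule: ExclusionRule = ExclusionRule(),
) -> np.ndarray:
    """Boolean outlier flags for per-trial adaptation effects.

    A trial is excluded iff effect > c + p_t when p_t >= 0, or
    effect < -c + p_t when p_t < 0.  NaN effects are never flagged here
    (they are already unusable upstream).
    """
    e = np.asarray(effects, dtype=float)
    p = np.asarray(rotations, dtype=float)
    if e.shape != p.shape:
        raise ValueError("effects and rotations must align")
    with np.errstate(invalid="ignore"):
        flags = np.where(p >= 0, e > rule.bound_c + p, e < -rule.bound_c + p)
    return flags & np.isfinite(e)


def build_adaptation_curve(
    cw_effects: Sequence[float] | np.ndarray,
    ccw_effects: Sequence[float] | np.ndarray,
    cw_excluded: Sequence[bool] | np.ndarray,
    ccw_excluded: Sequence[bool] | np.ndarray,
    subject_id: str = "",
) -> AdaptationCurve:
    """Average CW and sign-flipped CCW effects trial-by-trial.

    Where exactly one block's trial is excluded the other supplies the
    entry (tags ``cw_only`` / ``ccw_only``); where both are excluded the
    entry is missing.
    """
    cw = np.asarray(cw_effects, dtype=float)
    ccw = np.asarray(ccw_effects, dtype=float)
    cw_ok = ~np.asarray(cw_excluded, dtype=bool) & np.isfinite(cw)
    ccw_ok = ~np.asarray(ccw_excluded, dtype=bool) & np.isfinite(ccw)
    if not (cw.shape == ccw.shape == (40,)):
        raise ValueError("expected 40 aligned trials per block")
    flipped = -ccw
    values = np.full(40, np.nan)
    source = np.empty(40, dtype=object)
    both = cw_ok & ccw_ok
    values[both] = (cw[both] + flipped[both]) / 2.0
    source[both] = "both"
    only_cw = cw_ok & ~ccw_ok
    values[only_cw] = cw[only_cw]
    source[only_cw] = "cw_only"
    only_ccw = ~cw_ok & ccw_ok
    values[only_ccw] = flipped[only_ccw]
    source[only_ccw] = "ccw_only"
    source[~cw_ok & ~ccw_ok] = "missing"
    return AdaptationCurve(subject_id=subject_id, values=values, source=source)


def score_trial(log, te_mode: str = "mean_abs") -> TrialFeatures:
    """Score one trial log into :class:`TrialFeatures`.

    Degenerate trials (no onset, zero variance, zero peak velocity) are
    returned flagged excluded with the reason instead of raising.
    """
    feats = TrialFeatures(
        subject_id=log.subject_id,
        block=log.block,
        trial=log.trial,
        block_trial=log.block_trial,
        rotation_deg=log.rotation_deg,
        target_angle_deg=log.target_angle_deg,
    )
    vy = _velocity(log.cursor_y_mm, log.time_s)
    try:
        onset = detect_onset(vy)
        peak, angle = movement_angle_at_peak(log, onset)
    except (DegenerateTrialError, NoOnsetError) as err:
        feats.excluded = True
        feats.exclusion_reason = str(err)
        return feats
    dt = float(np.median(np.diff(np.asarray(log.time_s, dtype=float))))
    feats.onset_frame = onset
    feats.peak_frame = peak
    feats.movement_angle_deg = angle
    feats.movement_time_ms = (peak - onset) * dt * 1000.0
    feats.trajectory_error_mm = trajectory_error(log, onset, mode=te_mode)
    if log.block in ("CW", "CCW"):
        feats.adaptation_effect_deg = adaptation_effect(angle, log.rotation_deg)
    return feats


def score_session(
    trial_logs: Iterable,
    rule: ExclusionRule = ExclusionRule(),
    te_mode: str = "mean_abs",
) -> pd.DataFrame:
    """Score every trial of a session and apply the outlier exclusion.

    Returns a features table (one row per trial).  Excluded adaptation
    trials have their adaptation effect blanked; the raw movement angle is
    retained.
    """
    rows = [score_trial(log, te_mode=te_mode) for log in trial_logs]
    df = pd.DataFrame([vars(f) for f in rows])
    adapt = df["block"].isin(["CW", "CCW"])
    flags = apply_exclusion(
        df.loc[adapt, "adaptation_effect_deg"].to_numpy(),
        df.loc[adapt, "rotation_deg"].to_numpy(),
        rule,
    )
    idx = df.index[adapt][flags]
    df.loc[idx, "excluded"] = True
    df.loc[idx, "exclusion_reason"] = "outlier"
    df.loc[df["excluded"] & adapt, "adaptation_effect_deg"] = np.nan
    return df


def session_curve(features: pd.DataFrame, subject_id: str | None = None) -> AdaptationCurve:
    """Build the CW/CCW-averaged adaptation curve from a features table."""
    if subject_id is None:
        subject_id = str(features["subject_id"].iloc[0])
    blocks = {}
    for label in ("CW", "CCW"):
        sub = features[features["block"] == label].sort_values("block_trial")
        if len(sub) != 40:
            raise ValueError(f"block {label} must have 40 trials")
        blocks[label] = sub
    return build_adaptation_curve(
        blocks["CW"]["adaptation_effect_deg"].to_numpy(),
        blocks["CCW"]["adaptation_effect_deg"].to_numpy(),
        blocks["CW"]["excluded"].to_numpy(),
        blocks["CCW"]["excluded"].to_numpy(),
        subject_id=subject_id,
    )
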