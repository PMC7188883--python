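"""Deterministic model of the tablet tilt-to-cursor task.

The device maps tablet tilt (read as accelerometer components ``a_x, a_y``)
to a cursor through a first-order exponential low-pass filter

    p <- retain * p + gain * arcsin(a) - offset        (per_step mode)
    p <- retain * p + gain * (arcsin(a) - offset)      (set_point mode)

with ``arcsin`` in degrees, followed by a visuomotor rotation of the
filtered tilt vector.  ``per_step`` is the recursion exactly as published
for the original tablet application; its fixed point is
``arcsin(a) - offset / gain``, which for the published y-offset of -30
degrees diverges far off screen, so simulation defaults to ``set_point``,
whose fixed point ``arcsin(a) - offset`` means a resting tilt of about 30
degrees toward the user centers the cursor.  Both are retained; the filter
algebra is otherwise identical.

Angles are degrees throughout.  Rotations use a clockwise-positive
convention on screen: rotating the straight-up vector (0, 1) by +90
degrees yields (1, 0).  Under this convention the clockwise perturbation
block carries non-negative rotation angles, matching the sign assumed by
the outlier-exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "DeviceParams",
    "TaskGeometry",
    "PerturbationSchedule",
    "SessionPlan",
    "filter_step",
    "filter_series",
    "invert_filter",
    "apply_rotation",
    "make_schedule",
    "make_session",
    "PRACTICE_TARGETS",
]

OffsetMode = Literal["per_step", "set_point"]

#: Target angles (degrees, screen polar convention: 90 = straight up)
#: used during the practice block.
PRACTICE_TARGETS = (60.0, 75.0, 90.0, 105.0, 120.0)


@dataclass(frozen=True)
class DeviceParams:
    """Constants of the tilt-to-cursor low-pass filter.

    ``filter_retain`` and ``filter_gain`` must sum to 1 (a convex,
    contraction-by-``retain`` filter).  Offsets are in degrees of tilt and
    set the trial's initial cursor position.
    """

    filter_retain: float = 0.95
    filter_gain: float = 0.05
    offset_x: float = 0.0
    offset_y: float = -30.0
    sample_rate: float = 200.0
    offset_mode: OffsetMode = "set_point"

    def __post_init__(self) -> None:
        if abs(self.filter_retain + self.filter_gain - 1.0) > 1e-12:
            raise ValueError("filter_retain + filter_gain must equal 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.offset_mode not in ("per_step", "set_point"):
            raise ValueError(f"unknown offset_mode {self.offset_mode!r}")


@dataclass(frozen=True)
class TaskGeometry:
    """Screen geometry of the reaching task.

    Distances are millimetres on the display.  ``tilt_gain_mm_per_deg``
    converts filtered tilt (degrees) to cursor displacement (mm); the
    physical gain of the original application is not published, so 1 mm
    per degree with a 50 mm target distance is used (reachable well within
    the 15-degree rotation headroom) and both are configurable.
    """

    cursor_radius: float = 4.5
    start_radius: float = 9.0
    target_radius: float = 4.5
    target_distance: float = 50.0
    tilt_gain_mm_per_deg: float = 1.0
    target_angles_practice: tuple[float, ...] = PRACTICE_TARGETS
    target_angle_adaptation: float = 90.0
    hold_duration: float = 1.0
    movement_limit: float = 2.0

    def __post_init__(self) -> None:
        if min(self.cursor_radius, self.start_radius, self.target_radius) <= 0:
            raise ValueError("all radii must be positive")
        if self.target_distance <= 0:
            raise ValueError("target_distance must be positive")
        if 90.0 not in self.target_angles_practice:
            raise ValueError("practice target set must contain 90 degrees")


@dataclass(frozen=True)
class PerturbationSchedule:
    """Per-trial visuomotor rotation angles for the 80 adaptation trials.

    ``angles`` is ordered by presentation; ``block_labels`` marks each
    trial CW or CCW; ``direction_first`` records the counterbalance order.
    CW angles are >= 0, CCW angles <= 0, |angle| <= 15, and consecutive
    angles on the ramp change by exactly one degree.
    """

    angles: np.ndarray
    block_labels: np.ndarray
    direction_first: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        object.__setattr__(self, "block_labels", np.asarray(self.block_labels, dtype=object))
        if self.angles.shape != (80,) or self.block_labels.shape != (80,):
            raise ValueError("schedule must cover exactly 80 trials")
        if np.max(np.abs(self.angles)) > 15:
            raise ValueError("rotation magnitude must not exceed 15 degrees")

    def block_angles(self, label: str) -> np.ndarray:
        """Within-block angle sequence (length 40) for ``label`` CW|CCW."""
        out = self.angles[self.block_labels == label]
        if out.shape != (40,):
            raise ValueError(f"block {label!r} does not have 40 trials")
        return out


@dataclass(frozen=True)
class SessionPlan:
    """Layout of one session: 20 practice trials then 80 adaptation trials."""

    practice_targets: np.ndarray
    schedule: PerturbationSchedule
    n_practice: int = 20
    n_adaptation: int = 80

    def __post_init__(self) -> None:
        if self.n_practice != 20 or self.n_adaptation != 80:
            raise ValueError("session is 20 practice + 80 adaptation trials")
        if len(self.practice_targets) != self.n_practice:
            raise ValueError("practice_targets must have 20 entries")


def _arcsin_deg(accel: np.ndarray | float) -> np.ndarray | float:
    a = np.asarray(accel, dtype=float)
    if np.any(np.abs(a) > 1.0):
        raise ValueError("accelerometer sample outside [-1, 1] (corrupt sample)")
    out = np.degrees(np.arcsin(a))
    return float(out) if np.isscalar(accel) or out.ndim == 0 else out


def filter_step(
    p_prev: float,
    accel: float,
    offset: float,
    params: DeviceParams = DeviceParams(),
) -> float:
    """One step of the tilt low-pass filter, in degrees.

    ``per_step`` mode subtracts the offset outside the gain (the published
    recursion); ``set_point`` subtracts it inside, making the fixed point
    ``arcsin(accel) - offset``.
    """
    u = _arcsin_deg(accel)
    if params.offset_mode == "per_step":
        return params.filter_retain * p_prev + params.filter_gain * u - offset
    return params.filter_retain * p_prev + params.filter_gain * (u - offset)


def filter_series(
    accel: Sequence[float] | np.ndarray,
    offset: float,
    params: DeviceParams = DeviceParams(),
    p0: float = 0.0,
) -> np.ndarray:
    """Run the filter over a whole accelerometer channel.

    Equivalent to iterating :func:`filter_step` from state ``p0``;
    implemented as an IIR filter for speed.
    """
    u = _arcsin_deg(np.asarray(accel, dtype=float))
    r, g = params.filter_retain, params.filter_gain
    if params.offset_mode == "per_step":
        x = g * u - offset
    else:
        x = g * (u - offset)
    # y[n] = x[n] + r*y[n-1]; zi carries the p0 initial condition
    y, _ = lfilter([1.0], [1.0, -r], x, zi=np.array([r * p0]))
    return y


def invert_filter(
    tilt_deg: np.ndarray,
    offset: float,
    params: DeviceParams = DeviceParams(),
    p0: float = 0.0,
) -> np.ndarray:
    """Accelerometer channel that makes the filter reproduce ``tilt_deg``.

    Analytic inverse of :func:`filter_series`: solves each step for
    ``arcsin(a)`` and maps back through sine.  Raises if the required
    instantaneous tilt leaves the arcsine range (trajectory too fast for
    the filter gain).
    """
    p = np.asarray(tilt_deg, dtype=float)
    prev = np.concatenate([[p0], p[:-1]])
    r, g = params.filter_retain, params.filter_gain
    if params.offset_mode == "per_step":
        u = (p - r * prev + offset) / g
    else:
        u = (p - r * prev) / g + offset
    if np.any(np.abs(u) > 90.0 + 1e-9):
        raise ValueError("trajectory not representable: |arcsin| would exceed 90 deg")
    return np.sin(np.radians(np.clip(u, -90.0, 90.0)))


def apply_rotation(vec: Sequence[float] | np.ndarray, rotation: float) -> np.ndarray:
    """Rotate a 2-vector (or (N, 2) array of vectors) clockwise by ``rotation`` degrees.

    Clockwise-positive: ``apply_rotation((0, 1), 90) == (1, 0)``.  With
    zero rotation the display position equals the tilt-space position.
    """
    if not np.isfinite(rotation):
        raise ValueError("rotation must be finite")
    v = np.asarray(vec, dtype=float)
    th = np.radians(rotation)
    c, s = np.cos(th), np.sin(th)
    rot = np.array([[c, s], [-s, c]])
    return v @ rot.T


def _triangle_block() -> np.ndarray:
    # |p_t| = t (t=1..15), 30 - t (t=16..30), 0 (t=31..40)
    t = np.arange(1, 41)
    return np.where(t <= 15, t, np.where(t <= 30, 30 - t, 0)).astype(float)


def make_schedule(direction_first: str = "CW") -> PerturbationSchedule:
    """Triangular ramp schedule: up 1..15 deg, down to 0 by trial 30, zero 31..40.

    One 40-trial clockwise block (angles >= 0) and one counterclockwise
    block (negated), ordered by ``direction_first``.
    """
    if direction_first not in ("CW", "CCW"):
        raise ValueError("direction_first must be 'CW' or 'CCW'")
    tri = _triangle_block()
    blocks = {"CW": tri, "CCW": -tri}
    second = "CCW" if direction_first == "CW" else "CW"
    angles = np.concatenate([blocks[direction_first], blocks[second]])
    labels = np.array([direction_first] * 40 + [second] * 40, dtype=object)
    return PerturbationSchedule(angles=angles, block_labels=labels, direction_first=direction_first)


def make_session(
    direction_first: str = "CW",
    seed: int | np.random.SeedSequence = 0,
    geometry: TaskGeometry = TaskGeometry(),
) -> SessionPlan:
    """Build a session plan: pseudorandom practice targets + the schedule.

    Practice targets are a seeded balanced shuffle (each of the five
    angles appears four times in random order), with zero rotation;
    adaptation trials all aim at 90 degrees.  Reproducible for fixed seed.
    """
    rng = np.random.default_rng(seed)
    reps = np.repeat(geometry.target_angles_practice, 4)
    targets = rng.permutation(reps)
    return SessionPlan(practice_targets=targets, schedule=make_schedule(direction_first))
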