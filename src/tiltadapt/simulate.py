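"""Synthetic participants for the gradual visuomotor-rotation task.

The generator stands in for the unreleased cohort data.  Each subject is
a delayed-gain adapter: on trial t of a block the internally compensated
angle is ``e*_t = amp * p_{t-delay} + N(0, noise_sd^2)`` where ``p`` is
the within-block rotation schedule (``p_{<=0} = 0``).  A state-space
learner is deliberately not used: under this gradually rising and
vanishing schedule the delayed-gain law is exactly identifiable by the
delay/amplitude/phase/RMSE decomposition, which is what the pipeline is
meant to recover.

Within a trial the subject holds the cursor at the start, then reaches
with a minimum-jerk (bell-shaped) speed profile along a tilt-space
heading that deviates from the target line by ``-e*_t`` (compensation),
and finally steers the displayed cursor toward the target with a
proportional feedback correction.  The accelerometer channel is the
analytic inverse of the device filter, so running the device model on a
generated log reproduces the stored cursor path to numerical precision.

Occasional outlier trials encode an aim error placed 20-40 degrees beyond
the outlier-exclusion bound, so the exclusion rule catches them by
construction.  Outlier trials never coincide across the CW and CCW blocks
of a subject (coincident outliers would leave a hole in the averaged
curve; the cohorts this emulates showed none).

Group presets follow the reported cohort summaries: amplitude 0.91/0.75/
0.72, delay 3/4/5 trials and movement time 109/96/51 ms for the PD,
elderly and young groups respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .device import (
    DeviceParams,
    PerturbationSchedule,
    SessionPlan,
    TaskGeometry,
    apply_rotation,
    invert_filter,
    make_session,
)
from .io import META_COLUMNS, TrialLog

__all__ = [
    "SubjectPreset",
    "CohortSpec",
    "SimulatedSession",
    "CohortResult",
    "GROUP_PRESETS",
    "simulate_adaptation_series",
    "simulate_trial_trajectory",
    "simulate_session",
    "simulate_cohort",
    "demographics_table",
]

#: Multiplier from the preset movement time (onset to peak velocity) to
#: the total minimum-jerk reach duration.  The onset threshold crosses
#: high on the bell, so the detected onset-to-peak time is a fraction of
#: the reach duration; this scale places the detected movement times of
#: the group presets in their intended range.
MOVE_DURATION_SCALE = 4.5

OUTLIER_MARGIN = (20.0, 40.0)  # degrees beyond the exclusion bound
OUTLIER_BOUND_C = 15.0


@dataclass(frozen=True)
class SubjectPreset:
    """Generative parameters of one subject group."""

    group: str
    amp_true: float
    delay_true: int
    noise_sd: float = 1.5
    movement_time_mean: float = 96.0  # ms, onset to peak velocity
    movement_time_sd: float = 25.0  # ms, between-trial spread
    outlier_rate: float = 0.04
    feedback_gain: float = 0.8

    def __post_init__(self) -> None:
        if self.amp_true < 0:
            raise ValueError("amp_true must be >= 0")
        if self.delay_true < 0 or int(self.delay_true) != self.delay_true:
            raise ValueError("delay_true must be a non-negative integer")
        if not (0 <= self.outlier_rate < 0.5):
            raise ValueError("outlier_rate must be in [0, 0.5)")
        if not (0 <= self.feedback_gain <= 1):
            raise ValueError("feedback_gain must be in [0, 1]")


#: Cohort presets (amplitude/delay/movement time from the reported group
#: summaries; movement-time SDs are the reported s.e.m. times sqrt(18)).
GROUP_PRESETS: dict[str, SubjectPreset] = {
    "PD": SubjectPreset("PD", amp_true=0.91, delay_true=3, movement_time_mean=109.0, movement_time_sd=29.0),
    "elderly": SubjectPreset("elderly", amp_true=0.75, delay_true=4, movement_time_mean=96.0, movement_time_sd=34.0),
    "young": SubjectPreset("young", amp_true=0.72, delay_true=5, movement_time_mean=51.0, movement_time_sd=14.0),
}

#: Demographic targets per group: mean, SD per attribute (None = not recorded).
_DEMOGRAPHICS = {
    "PD": {
        "age": (70.06, 7.34),
        "MMSE": (27.78, 2.07),
        "UPDRS": (26.06, 12.07),
        "HY": (2.67, 0.69),
        "duration": (6.72, 4.32),
        "male_frac": 9 / 18,
    },
    "elderly": {
        "age": (75.67, 12.70),
        "MMSE": (27.72, 2.45),
        "UPDRS": None,
        "HY": None,
        "duration": None,
        "male_frac": 8 / 18,
    },
    "young": {
        "age": (21.33, 1.50),
        "MMSE": None,
        "UPDRS": None,
        "HY": None,
        "duration": None,
        "male_frac": 16 / 18,
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: three groups, counterbalanced rotation order."""

    n_per_group: int = 18
    master_seed: int = 0
    groups: tuple[str, ...] = ("PD", "elderly", "young")

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


@dataclass
class SimulatedSession:
    """One subject's simulated session plus the generative ground truth.

    ``truth`` has one row per adaptation trial with the realized
    adaptation state ``e_star`` (including trial noise), the encoded
    movement effect (differing from ``e_star`` only on outlier trials)
    and the outlier flag.  Recovery tests read it instead of re-deriving.
    """

    meta: dict
    trials: list[TrialLog]
    truth: pd.DataFrame


@dataclass
class CohortResult:
    sessions: list[SimulatedSession]
    demographics: pd.DataFrame


def simulate_adaptation_series(
    preset: SubjectPreset,
    schedule: PerturbationSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-trial adaptation state for the 80 adaptation trials.

    Delayed-gain law applied independently within each block (the delay
    does not carry across the CW/CCW boundary; rotations before a block's
    first trial are zero).
    """
    if len(schedule.angles) != 80:
        raise ValueError("schedule must cover 80 trials")
    out = np.empty(80)
    pos = 0
    for label in (schedule.direction_first, "CCW" if schedule.direction_first == "CW" else "CW"):
        p = schedule.block_angles(label)
        d = int(preset.delay_true)
        delayed = np.concatenate([np.zeros(d), p[: 40 - d]]) if d > 0 else p
        out[pos : pos + 40] = preset.amp_true * delayed + rng.normal(0.0, preset.noise_sd, 40)
        pos += 40
    return out


def _dir_cw(theta_cw_deg: float) -> np.ndarray:
    """Unit vector at clockwise angle ``theta`` from straight up (+y)."""
    th = np.radians(theta_cw_deg)
    return np.array([np.sin(th), np.cos(th)])


def _minimum_jerk_path(distance: float, n_frames: int) -> np.ndarray:
    tau = np.arange(1, n_frames + 1) / n_frames
    return distance * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def simulate_trial_trajectory(
    effect_deg: float,
    rotation_deg: float,
    geometry: TaskGeometry,
    device: DeviceParams,
    preset: SubjectPreset,
    rng: np.random.Generator,
    target_angle_deg: float = 90.0,
    subject_id: str = "sim",
    group: str = "sim",
    block: str = "CW",
    trial: int = 1,
    block_trial: int = 1,
) -> TrialLog:
    """Generate one trial's 200-Hz log.

    The tilt-space heading is the target line rotated by ``-effect_deg``
    (clockwise-positive), so the displayed movement angle at peak
    velocity is ``rotation_deg - effect_deg`` and the scored adaptation
    effect recovers ``effect_deg``.
    """
    if abs(effect_deg) >= 90:
        raise ValueError("|effect| must be < 90 degrees")
    if geometry.target_distance <= 0:
        raise ValueError("degenerate geometry: zero target distance")
    fs = device.sample_rate
    n_hold = int(round(geometry.hold_duration * fs))
    n_window = int(round(geometry.movement_limit * fs))  # trial spans the full window

    mt_ms = max(float(rng.normal(preset.movement_time_mean, preset.movement_time_sd)), 20.0)
    # Lower bound keeps the reach representable by the accelerometer
    # (peak per-frame tilt change divided by the filter gain must stay
    # inside the arcsine range: ~0.18 s for a 50 mm reach at 200 Hz);
    # upper bound keeps the reach a small enough fraction of the trial
    # that the onset threshold (trial mean + 2.5 SD) still crosses the
    # velocity bell.
    move_s = float(np.clip(mt_ms / 1000.0 * MOVE_DURATION_SCALE, 0.18, 0.45 * geometry.movement_limit))
    n_move = max(int(round(move_s * fs)), 8)
    n_fb = n_window - n_move

    theta_target = 90.0 - target_angle_deg  # clockwise angle from +y
    theta_tilt = theta_target - effect_deg
    reach = _minimum_jerk_path(geometry.target_distance, n_move)
    tilt_move = np.outer(reach, _dir_cw(theta_tilt))  # (n_move, 2) mm

    disp_move = apply_rotation(tilt_move, rotation_deg)
    target_pt = geometry.target_distance * _dir_cw(theta_target)
    # Smooth online correction: a minimum-jerk displacement covering
    # feedback_gain of the residual error over the rest of the window.
    # Its velocity is zero at both ends and far below the reach peak, so
    # the peak-velocity frame always falls inside the ballistic reach.
    d_end = disp_move[-1]
    correction = preset.feedback_gain * (target_pt - d_end)
    disp_fb = d_end + np.outer(_minimum_jerk_path(1.0, n_fb), correction)
    tilt_fb = apply_rotation(disp_fb, -rotation_deg)

    tilt = np.vstack([np.zeros((n_hold, 2)), tilt_move, tilt_fb])
    display = np.vstack([np.zeros((n_hold, 2)), disp_move, disp_fb])

    tilt_deg_x = tilt[:, 0] / geometry.tilt_gain_mm_per_deg
    tilt_deg_y = tilt[:, 1] / geometry.tilt_gain_mm_per_deg
    accel_x = invert_filter(tilt_deg_x, device.offset_x, device)
    accel_y = invert_filter(tilt_deg_y, device.offset_y, device)

    n = len(tilt)
    return TrialLog(
        subject_id=subject_id,
        group=group,
        block=block,
        trial=trial,
        block_trial=block_trial,
        rotation_deg=rotation_deg,
        target_angle_deg=target_angle_deg,
        frame=np.arange(n),
        time_s=np.arange(n) / fs,
        accel_x=accel_x,
        accel_y=accel_y,
        cursor_x_mm=display[:, 0],
        cursor_y_mm=display[:, 1],
    )


def _outlier_trials(rng: np.random.Generator, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint outlier trial indices (0-based within block) for CW and CCW."""
    k_cw = rng.binomial(40, rate)
    k_ccw = rng.binomial(40, rate)
    cw = rng.choice(40, size=k_cw, replace=False)
    remaining = np.setdiff1d(np.arange(40), cw)
    ccw = rng.choice(remaining, size=min(k_ccw, len(remaining)), replace=False)
    return np.sort(cw), np.sort(ccw)


def simulate_session(
    subject_id: str,
    preset: SubjectPreset,
    direction_first: str = "CW",
    seed: int | np.random.SeedSequence = 0,
    geometry: TaskGeometry = TaskGeometry(),
    device: DeviceParams = DeviceParams(),
    include_practice: bool = True,
) -> SimulatedSession:
    """Simulate a full session (20 practice + 80 adaptation trials)."""
    rng = np.random.default_rng(seed)
    plan: SessionPlan = make_session(direction_first, seed=rng.integers(2**31), geometry=geometry)
    schedule = plan.schedule
    e_star = simulate_adaptation_series(preset, schedule, rng)

    out_by_block = dict(zip(("CW", "CCW"), (None, None)))
    cw_out, ccw_out = _outlier_trials(rng, preset.outlier_rate)
    out_by_block = {"CW": set(cw_out.tolist()), "CCW": set(ccw_out.tolist())}

    trials: list[TrialLog] = []
    truth_rows = []
    trial_no = 0
    if include_practice:
        for i, target in enumerate(plan.practice_targets, start=1):
            trial_no += 1
            trials.append(
                simulate_trial_trajectory(
                    0.0, 0.0, geometry, device, preset, rng,
                    target_angle_deg=float(target),
                    subject_id=subject_id, group=preset.group,
                    block="practice", trial=trial_no, block_trial=i,
                )
            )
    else:
        trial_no = 20

    block_counter: dict[str, int] = {"CW": 0, "CCW": 0}
    for i in range(80):
        trial_no += 1
        label = str(schedule.block_labels[i])
        block_counter[label] += 1
        bt = block_counter[label]
        p_t = float(schedule.angles[i])
        e_t = float(e_star[i])
        is_out = (bt - 1) in out_by_block[label]
        if is_out:
            # Aim error signed so the one-sided exclusion branch for this
            # trial's rotation sign (>= 0 or < 0) can catch it.
            margin = rng.uniform(*OUTLIER_MARGIN)
            if p_t >= 0:
                encoded = OUTLIER_BOUND_C + p_t + margin
            else:
                encoded = -OUTLIER_BOUND_C + p_t - margin
        else:
            encoded = e_t
        trials.append(
            simulate_trial_trajectory(
                encoded, p_t, geometry, device, preset, rng,
                target_angle_deg=geometry.target_angle_adaptation,
                subject_id=subject_id, group=preset.group,
                block=label, trial=trial_no, block_trial=bt,
            )
        )
        truth_rows.append(
            {
                "subject_id": subject_id,
                "trial": trial_no,
                "block": label,
                "block_trial": bt,
                "rotation_deg": p_t,
                "e_star": e_t,
                "encoded_effect": encoded,
                "is_outlier": is_out,
            }
        )

    meta = {
        "subject_id": subject_id,
        "group": preset.group,
        "direction_first": direction_first,
        "amp_true": preset.amp_true,
        "delay_true": preset.delay_true,
        "noise_sd": preset.noise_sd,
    }
    return SimulatedSession(meta=meta, trials=trials, truth=pd.DataFrame(truth_rows))


def _round_half(x: np.ndarray) -> np.ndarray:
    return np.round(x * 2) / 2


def demographics_table(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Table-style demographics: per-group Gaussian draws, clipped and rounded.

    MMSE is integer in [23, 30] (the inclusion criterion admits only
    scores above 22), UPDRS integer >= 0, H&Y on a half-point scale in
    [1, 5], disease duration >= 0.  Attributes not recorded for a group
    are left missing.
    """
    rows = []
    for group in spec.groups:
        targets = _DEMOGRAPHICS[group]
        n = spec.n_per_group
        n_male = int(round(targets["male_frac"] * n))
        sexes = rng.permutation(np.array(["M"] * n_male + ["F"] * (n - n_male)))
        for i in range(n):
            row = {"subject_id": f"{group}{i + 1:02d}", "group": group, "sex": sexes[i]}
            for attr in ("age", "MMSE", "UPDRS", "HY", "duration"):
                tgt = targets[attr]
                if tgt is None:
                    row[attr] = np.nan
                    continue
                value = rng.normal(*tgt)
                if attr == "age":
                    value = float(np.clip(np.round(value), 18, 95))
                elif attr == "MMSE":
                    value = float(np.clip(np.round(value), 23, 30))
                elif attr == "UPDRS":
                    value = float(np.clip(np.round(value), 0, 108))
                elif attr == "HY":
                    value = float(np.clip(_round_half(value), 1, 5))
                else:  # duration
                    value = float(np.clip(np.round(value, 1), 0.1, None))
                row[attr] = value
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec,
    presets: dict[str, SubjectPreset] | None = None,
    geometry: TaskGeometry = TaskGeometry(),
    device: DeviceParams = DeviceParams(),
    include_practice: bool = True,
) -> CohortResult:
    """Simulate the full three-group cohort.

    Each group is counterbalanced (alternating CW-first/CCW-first) and
    every subject gets an independent child seed of ``master_seed``, so
    the whole cohort is reproducible bit-for-bit.
    """
    presets = dict(GROUP_PRESETS if presets is None else presets)
    root = np.random.SeedSequence(spec.master_seed)
    demo_seed, *subject_seeds = root.spawn(1 + len(spec.groups) * spec.n_per_group)
    demographics = demographics_table(spec, np.random.default_rng(demo_seed))

    sessions: list[SimulatedSession] = []
    seed_iter = iter(subject_seeds)
    direction_col = []
    for group in spec.groups:
        preset = presets[group]
        for i in range(spec.n_per_group):
            direction = "CW" if i % 2 == 0 else "CCW"
            subject_id = f"{group}{i + 1:02d}"
            sessions.append(
                simulate_session(
                    subject_id, preset, direction_first=direction,
                    seed=next(seed_iter), geometry=geometry, device=device,
                    include_practice=include_practice,
                )
            )
            direction_col.append(direction)
    demographics = demographics.copy()
    demographics["direction_first"] = direction_col
    demographics = demographics[META_COLUMNS]
    return CohortResult(sessions=sessions, demographics=demographics)
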