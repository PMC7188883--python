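"""Decomposition of an adaptation curve into delay, amplitude, phase and RMSE.

A subject's 40-trial CW/CCW-averaged adaptation curve ``x = (x_1..x_40)``
is compared with the fragment ``p = (p_9..p_32)`` of the perturbation
schedule.  The temporal delay is the integer lag minimizing the mean
squared error between the lag-shifted curve fragment and ``p``; the
amplitude is the ratio of Euclidean norms; the phase is the arccosine of
the cosine similarity; the RMSE is the root mean squared residual at the
best lag.  Trial indices are 1-based to match the x_1..x_40 convention
used in the file formats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FragmentSpec",
    "DecompositionResult",
    "MissingDataError",
    "delay_argmin",
    "amplitude",
    "phase",
    "rmse",
    "decompose",
]


class MissingDataError(ValueError):
    """A fragment window needed by the delay search has a missing entry."""


@dataclass(frozen=True)
class FragmentSpec:
    """Window of the schedule used for the decomposition.

    1-based inclusive trial indices.  ``delay_max`` defaults to 8, the
    largest lag for which ``x_{end+delay}`` still exists in a 40-trial
    curve.
    """

    start: int = 9
    end: int = 32
    delay_min: int = 0
    delay_max: int = 8

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end):
            raise ValueError("need 1 <= start < end")
        if self.delay_min < 0 or self.delay_max < self.delay_min:
            raise ValueError("need 0 <= delay_min <= delay_max")
        if self.end + self.delay_max > 40:
            raise ValueError("delay_max would shift the window past trial 40")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DecompositionResult:
    delay: int
    amplitude: float
    phase_deg: float
    cos_phase: float
    rmse: float


def _curve_values(curve) -> np.ndarray:
    """Accept an AdaptationCurve or a plain length-40 array."""
    values = getattr(curve, "values", curve)
    values = np.asarray(values, dtype=float)
    if values.shape != (40,):
        raise ValueError("adaptation curve must have 40 entries")
    return values


def _fragment(values: np.ndarray, spec: FragmentSpec, delay: int) -> np.ndarray:
    # 1-based trials start+delay .. end+delay
    return values[spec.start + delay - 1 : spec.end + delay]


def _schedule_fragment(schedule_block: np.ndarray, spec: FragmentSpec) -> np.ndarray:
    p = np.asarray(schedule_block, dtype=float)
    if p.shape != (40,):
        raise ValueError("schedule block must have 40 entries")
    return p[spec.start - 1 : spec.end]


def delay_argmin(curve, schedule_block: np.ndarray, spec: FragmentSpec = FragmentSpec()) -> int:
    """Exhaustive integer-lag search minimizing the fragment MSE.

    Ties break toward the smallest lag.  Raises :class:`MissingDataError`
    if any candidate window contains a missing (NaN) entry.
    """
    values = _curve_values(curve)
    p = _schedule_fragment(schedule_block, spec)
    best_delay, best_mse = None, np.inf
    for delay in range(spec.delay_min, spec.delay_max + 1):
        window = _fragment(values, spec, delay)
        if np.any(~np.isfinite(window)):
            raise MissingDataError(f"missing curve entry in window for delay {delay}")
        mse = float(np.mean((window - p) ** 2))
        if mse < best_mse:
            best_delay, best_mse = delay, mse
    return int(best_delay)


def amplitude(x_frag: np.ndarray, p_frag: np.ndarray) -> float:
    """Norm ratio |x|/|p| over the aligned fragments (response strength)."""
    x = np.asarray(x_frag, dtype=float)
    p = np.asarray(p_frag, dtype=float)
    norm_p = float(np.linalg.norm(p))
    if norm_p == 0.0:
        raise ValueError("schedule fragment has zero norm")
    return float(np.linalg.norm(x)) / norm_p


def phase(x_frag: np.ndarray, p_frag: np.ndarray) -> float:
    """Arccosine similarity between the fragments, in degrees [0, 180]."""
    x = np.asarray(x_frag, dtype=float)
    p = np.asarray(p_frag, dtype=float)
    nx, np_ = np.linalg.norm(x), np.linalg.norm(p)
    if nx == 0.0 or np_ == 0.0:
        raise ValueError("cannot compute phase of a zero-norm fragment")
    cos = float(np.dot(x, p) / (nx * np_))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def rmse(x_frag: np.ndarray, p_frag: np.ndarray) -> float:
    """Root mean squared residual between the aligned fragments (degrees)."""
    x = np.asarray(x_frag, dtype=float)
    p = np.asarray(p_frag, dtype=float)
    return float(np.sqrt(np.mean((x - p) ** 2)))


def decompose(curve, schedule_block: np.ndarray, spec: FragmentSpec = FragmentSpec()) -> DecompositionResult:
    """Full decomposition: best lag, then amplitude/phase/RMSE at that lag."""
    values = _curve_values(curve)
    p = _schedule_fragment(schedule_block, spec)
    delay = delay_argmin(values, schedule_block, spec)
    x = _fragment(values, spec, delay)
    phi = phase(x, p)
    return DecompositionResult(
        delay=delay,
        amplitude=amplitude(x, p),
        phase_deg=phi,
        cos_phase=float(np.cos(np.radians(phi))),
        rmse=rmse(x, p),
    )
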