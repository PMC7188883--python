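"""Group-level statistics for adaptation-curve analyses.

Per-trial one-sample t-tests against zero (with multiplicity correction
across the 40 trials) locate the window of significant adaptation; group
comparisons use one-way fixed-effects ANOVA with Tukey HSD post hoc
tests; demographic comparisons use pooled-variance two-sample t-tests
(also available from summary statistics alone, for published-table
checks); associations use Pearson and Spearman correlations; movement
times are z-scored within group before pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WindowResult",
    "GroupComparison",
    "CorrelationResult",
    "significant_window",
    "window_mean",
    "anova_tukey",
    "two_sample_t",
    "two_sample_t_from_stats",
    "correlations",
    "zscore_within_group",
]


@dataclass(frozen=True)
class WindowResult:
    """Longest contiguous run of trials whose corrected p <= alpha.

    ``window`` is a 1-based inclusive (start, end) trial range, or None
    when no trial is significant.  Isolated significant trials outside
    the longest run are listed in ``significant_trials`` but do not widen
    the window.
    """

    window: tuple[int, int] | None
    p_raw: np.ndarray
    p_corrected: np.ndarray
    alpha: float
    significant_trials: tuple[int, ...]

    @property
    def trials(self) -> np.ndarray:
        if self.window is None:
            return np.array([], dtype=int)
        return np.arange(self.window[0], self.window[1] + 1)


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    F: float
    df: tuple[int, int]
    p_anova: float
    group_names: tuple[str, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    tukey_p: dict[tuple[str, str], float]


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def significant_window(
    curves: np.ndarray | Sequence,
    alpha: float = 0.01,
    correction: str = "bonferroni",
) -> WindowResult:
    """Find the contiguous trial window significantly different from zero.

    ``curves`` is (n_subjects, 40); missing entries (NaN) are dropped per
    trial.  A two-sided one-sample t-test is run per trial, corrected
    across the 40 trials (``bonferroni`` default, ``holm`` or ``none``),
    and the longest contiguous run with corrected p < alpha is returned.
    """
    arr = np.vstack([np.asarray(getattr(c, "values", c), dtype=float) for c in np.atleast_2d(curves)]) \
        if not isinstance(curves, np.ndarray) else np.asarray(curves, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 40:
        raise ValueError("curves must be (n_subjects, 40)")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    p_raw = np.empty(40)
    for t in range(40):
        col = arr[:, t]
        col = col[np.isfinite(col)]
        if col.size < 2:
            raise ValueError(f"trial {t + 1}: fewer than 2 non-missing values")
        p_raw[t] = sps.ttest_1samp(col, 0.0).pvalue
    if correction == "none":
        p_corr = p_raw.copy()
    elif correction in ("bonferroni", "holm"):
        p_corr = multipletests(p_raw, method=correction)[1]
    else:
        raise ValueError("correction must be 'bonferroni', 'holm' or 'none'")
    # <= so that corrected p-values clipped at 1.0 pass a vacuous alpha of 1
    sig = p_corr <= alpha
    window = _longest_run(sig)
    return WindowResult(
        window=window,
        p_raw=p_raw,
        p_corrected=p_corr,
        alpha=alpha,
        significant_trials=tuple(int(t + 1) for t in np.nonzero(sig)[0]),
    )


def _longest_run(mask: np.ndarray) -> tuple[int, int] | None:
    best, cur_start, best_len = None, None, 0
    for i, flag in enumerate(np.concatenate([mask, [False]])):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if i - cur_start > best_len:
                best, best_len = (cur_start + 1, i), i - cur_start  # 1-based inclusive
            cur_start = None
    return best


def window_mean(curve, window: tuple[int, int] | WindowResult) -> float:
    """Mean curve value over a 1-based inclusive trial window (NaNs skipped)."""
    if isinstance(window, WindowResult):
        window = window.window
    if window is None:
        raise ValueError("empty window")
    start, end = window
    if end < start:
        raise ValueError("empty window")
    values = np.asarray(getattr(curve, "values", curve), dtype=float)[start - 1 : end]
    if not np.any(np.isfinite(values)):
        raise ValueError("window has no finite values")
    return float(np.nanmean(values))


def anova_tukey(samples: dict[str, Sequence[float]]) -> GroupComparison:
    """One-way fixed-effects ANOVA followed by Tukey HSD on all pairs."""
    names = tuple(samples.keys())
    groups = [np.asarray(samples[name], dtype=float) for name in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance in every group")
    n_total = sum(len(g) for g in groups)
    df = (len(groups) - 1, n_total - len(groups))
    f_res = sps.f_oneway(*groups)
    tk = sps.tukey_hsd(*groups)
    tukey_p = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            tukey_p[(names[i], names[j])] = float(tk.pvalue[i, j])
    return GroupComparison(
        F=float(f_res.statistic),
        df=df,
        p_anova=float(f_res.pvalue),
        group_names=names,
        means=tuple(float(np.mean(g)) for g in groups),
        sems=tuple(float(sps.sem(g)) for g in groups),
        tukey_p=tukey_p,
    )


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics: (t, df, two-sided p).

    Pooled-variance by default (the convention the published demographic
    tables follow); Welch with ``equal_var=False``.  Degenerate inputs
    with both SDs zero use the convention p = 1 for equal means and
    p = 0 otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both samples")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float("inf"), float(n1 + n2 - 2), 0.0
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sample t-test on raw samples: (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_t_from_stats(
        float(np.mean(x)), float(np.std(x, ddof=1)), len(x),
        float(np.mean(y)), float(np.std(y, ddof=1)), len(y),
        equal_var=equal_var,
    )


def correlations(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson and Spearman correlations with two-sided p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input")
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    return CorrelationResult(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )


def zscore_within_group(
    values: Sequence[float], groups: Sequence, ddof: int = 1
) -> np.ndarray:
    """Z-score values within each group, then pool (order preserved).

    Each group's normalized values have mean 0 and SD 1 (sample SD by
    default, matching the usual normalization before pooled
    correlations).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    out = np.empty_like(v)
    for label in np.unique(g):
        mask = g == label
        if mask.sum() < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        sd = np.std(v[mask], ddof=ddof)
        if sd == 0:
            raise ValueError(f"group {label!r} has zero variance")
        out[mask] = (v[mask] - np.mean(v[mask])) / sd
    return out
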