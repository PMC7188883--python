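"""End-to-end pipeline: simulate (or load) -> extract -> decompose -> stats.

``run_pipeline`` executes the whole analysis and writes every
intermediate table as CSV plus a run manifest (seed, configuration hash,
package and library versions), so a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decomposition import FragmentSpec, decompose
from .device import DeviceParams, TaskGeometry, make_schedule
from .io import read_subject_meta, read_trial_logs, write_subject_meta, write_trial_logs
from .kinematics import AdaptationCurve, ExclusionRule, score_session, session_curve
from .simulate import GROUP_PRESETS, CohortSpec, SubjectPreset, simulate_cohort
from .stats import anova_tukey, correlations, significant_window, window_mean, zscore_within_group

__all__ = ["default_config", "run_pipeline", "PipelineResult"]


def default_config() -> dict:
    """Baseline configuration; any subset may be overridden."""
    return {
        "cohort": {"n_per_group": 18, "groups": ["PD", "elderly", "young"]},
        "presets": {},  # per-group overrides of the built-in presets
        "device": {"offset_mode": "set_point"},
        "geometry": {},
        "exclusion_c": 15.0,
        "te_mode": "mean_abs",
        "fragment": {"start": 9, "end": 32, "delay_min": 0, "delay_max": 8},
        "stats": {"alpha": 0.01, "correction": "bonferroni", "window_group": "PD"},
        "io": {"write_trial_logs": False},
        "input_dir": None,
    }


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _config_hash(config: dict, seed: int) -> str:
    blob = json.dumps({"config": config, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: dict
    features: pd.DataFrame
    curves: dict[str, AdaptationCurve]
    decomposition: pd.DataFrame
    subjects: pd.DataFrame
    window: object
    group_tests: dict[str, object]
    correlation_table: pd.DataFrame
    manifest: dict


def _curves_frame(curves: dict[str, AdaptationCurve]) -> pd.DataFrame:
    rows = []
    for sid, curve in curves.items():
        for t in range(40):
            rows.append(
                {
                    "subject_id": sid,
                    "trial": t + 1,
                    "value": curve.values[t],
                    "source": curve.source[t],
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: dict | None = None, seed: int = 0, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis; write tables and a manifest if ``out_dir`` given."""
    cfg = _merge(default_config(), config)
    device = DeviceParams(**cfg["device"])
    geometry = TaskGeometry(**{k: tuple(v) if isinstance(v, list) else v for k, v in cfg["geometry"].items()})
    rule = ExclusionRule(bound_c=cfg["exclusion_c"])
    frag = FragmentSpec(**cfg["fragment"])

    if cfg["input_dir"]:
        in_dir = Path(cfg["input_dir"])
        sessions_by_subject = read_trial_logs(in_dir / "trial_logs.csv")
        subjects = read_subject_meta(in_dir / "subjects.csv")
        sessions = [(sid, logs) for sid, logs in sessions_by_subject.items()]
        group_of = dict(zip(subjects["subject_id"], subjects["group"]))
        truth = None
    else:
        presets = {
            name: (SubjectPreset(**{"group": name, **p}) if isinstance(p, dict) else p)
            for name, p in ({**GROUP_PRESETS, **cfg["presets"]}).items()
        }
        spec = CohortSpec(
            n_per_group=int(cfg["cohort"]["n_per_group"]),
            master_seed=int(seed),
            groups=tuple(cfg["cohort"]["groups"]),
        )
        cohort = simulate_cohort(spec, presets=presets, geometry=geometry, device=device)
        subjects = cohort.demographics
        sessions = [(s.meta["subject_id"], s.trials) for s in cohort.sessions]
        group_of = dict(zip(subjects["subject_id"], subjects["group"]))
        truth = pd.concat([s.truth for s in cohort.sessions], ignore_index=True)

    # --- extract ---------------------------------------------------------
    feature_parts, curves = [], {}
    for sid, logs in sessions:
        try:
            feats = score_session(logs, rule=rule, te_mode=cfg["te_mode"])
            curves[sid] = session_curve(feats, subject_id=sid)
        except Exception as err:  # abort with stage context
            raise RuntimeError(f"extract stage failed for subject {sid}: {err}") from err
        feature_parts.append(feats)
    features = pd.concat(feature_parts, ignore_index=True)

    # --- decompose -------------------------------------------------------
    schedule_cw = make_schedule("CW").block_angles("CW")
    rows = []
    for sid, curve in curves.items():
        try:
            res = decompose(curve, schedule_cw, frag)
        except Exception as err:
            raise RuntimeError(f"decompose stage failed for subject {sid}: {err}") from err
        rows.append(
            {
                "subject_id": sid,
                "group": group_of.get(sid, ""),
                "delay": res.delay,
                "amplitude": res.amplitude,
                "phase_deg": res.phase_deg,
                "cos_phase": res.cos_phase,
                "rmse": res.rmse,
            }
        )
    decomposition = pd.DataFrame(rows)

    # --- stats -----------------------------------------------------------
    stats_cfg = cfg["stats"]
    window_group = stats_cfg["window_group"]
    groups_present = list(dict.fromkeys(group_of.values()))
    if window_group not in groups_present:
        window_group = groups_present[0]
    wg_curves = np.vstack(
        [curves[sid].values for sid in curves if group_of.get(sid) == window_group]
    )
    window = significant_window(wg_curves, alpha=stats_cfg["alpha"], correction=stats_cfg["correction"])

    per_subject = decomposition.set_index("subject_id")
    summary_rows = []
    for sid, curve in curves.items():
        adapt = features[(features["subject_id"] == sid) & features["block"].isin(["CW", "CCW"])]
        kept = adapt[~adapt["excluded"]]
        in_window = (
            kept[kept["block_trial"].isin(window.trials)] if window.window else kept.iloc[:0]
        )
        summary_rows.append(
            {
                "subject_id": sid,
                "group": group_of.get(sid, ""),
                "window_mean_effect": window_mean(curve, window) if window.window else np.nan,
                "movement_time_ms": kept["movement_time_ms"].mean(),
                "trajectory_error_mm": in_window["trajectory_error_mm"].mean(),
                "n_excluded": int(adapt["excluded"].sum()),
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("subject_id")
    summary = summary.join(per_subject[["delay", "amplitude", "cos_phase", "rmse"]])

    group_tests = {}
    for metric in ("window_mean_effect", "amplitude", "cos_phase", "delay", "rmse", "movement_time_ms", "trajectory_error_mm"):
        by_group = {
            g: summary.loc[summary["group"] == g, metric].dropna().to_numpy()
            for g in groups_present
        }
        try:
            group_tests[metric] = anova_tukey(by_group)
        except ValueError as err:
            group_tests[metric] = None if "variance" in str(err) else err

    corr_rows = []
    pd_subjects = subjects[subjects["group"] == "PD"] if "PD" in groups_present else subjects.iloc[:0]
    if len(pd_subjects) >= 3:
        merged = pd_subjects.merge(summary.reset_index(), on="subject_id")
        for outcome in ("amplitude", "delay"):
            for score in ("age", "duration", "HY", "MMSE", "UPDRS"):
                pair = merged[[outcome, score]].dropna()
                if len(pair) >= 3 and pair[score].nunique() > 1 and pair[outcome].nunique() > 1:
                    res = correlations(pair[outcome], pair[score])
                    corr_rows.append(
                        {
                            "outcome": outcome,
                            "score": score,
                            "pearson_r": res.pearson_r,
                            "pearson_p": res.pearson_p,
                            "spearman_rho": res.spearman_rho,
                            "spearman_p": res.spearman_p,
                        }
                    )
    # movement time normalized within group vs amplitude, pooled
    mt_ok = summary.dropna(subset=["movement_time_ms", "amplitude"])
    if len(mt_ok) >= 6 and mt_ok["group"].nunique() >= 2:
        norm_mt = zscore_within_group(mt_ok["movement_time_ms"], mt_ok["group"])
        res = correlations(norm_mt, mt_ok["amplitude"])
        corr_rows.append(
            {
                "outcome": "amplitude",
                "score": "normalized_movement_time",
                "pearson_r": res.pearson_r,
                "pearson_p": res.pearson_p,
                "spearman_rho": res.spearman_rho,
                "spearman_p": res.spearman_p,
            }
        )
    correlation_table = pd.DataFrame(corr_rows)

    manifest = {
        "seed": int(seed),
        "config_hash": _config_hash(cfg, seed),
        "versions": {
            "tiltadapt": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_subjects": len(curves),
        "window": list(window.window) if window.window else None,
    }

    result = PipelineResult(
        config=cfg,
        features=features,
        curves=curves,
        decomposition=decomposition,
        subjects=subjects,
        window=window,
        group_tests=group_tests,
        correlation_table=correlation_table,
        manifest=manifest,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_subject_meta(subjects, out / "subjects.csv")
        features.to_csv(out / "features.csv", index=False, float_format="%.9g")
        _curves_frame(curves).to_csv(out / "curves.csv", index=False, float_format="%.9g")
        decomposition.to_csv(out / "decomposition.csv", index=False, float_format="%.9g")
        summary.reset_index().to_csv(out / "subject_summary.csv", index=False, float_format="%.9g")
        correlation_table.to_csv(out / "correlations.csv", index=False, float_format="%.9g")
        _write_report(out / "report.txt", result, summary)
        if cfg["io"]["write_trial_logs"] and not cfg["input_dir"]:
            all_logs = [log for _, logs in sessions for log in logs]
            write_trial_logs(all_logs, out / "trial_logs.csv")
            if truth is not None:
                truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.9g")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result


def _write_report(path: Path, result: PipelineResult, summary: pd.DataFrame) -> None:
    lines = [f"tiltadapt report (seed {result.manifest['seed']}, hash {result.manifest['config_hash']})"]
    w = result.window
    lines.append(
        f"significant window (corrected p < {w.alpha}): "
        + (f"trials {w.window[0]}-{w.window[1]}" if w.window else "none")
    )
    for metric, cmp in result.group_tests.items():
        if cmp is None or isinstance(cmp, Exception):
            lines.append(f"{metric}: not testable ({cmp})")
            continue
        means = ", ".join(
            f"{name} {m:.3f}+-{s:.3f}" for name, m, s in zip(cmp.group_names, cmp.means, cmp.sems)
        )
        pairs = "; ".join(f"{a} vs {b}: p={p:.4f}" for (a, b), p in cmp.tukey_p.items())
        lines.append(
            f"{metric}: F({cmp.df[0]},{cmp.df[1]}) = {cmp.F:.3f}, p = {cmp.p_anova:.4g} | {means} | {pairs}"
        )
    if len(result.correlation_table):
        lines.append("correlations (PD clinical scores & pooled movement time):")
        for _, row in result.correlation_table.iterrows():
            lines.append(
                f"  {row['outcome']} vs {row['score']}: r={row['pearson_r']:.3f} "
                f"(p={row['pearson_p']:.3f}), rho={row['spearman_rho']:.3f} (p={row['spearman_p']:.3f})"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
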