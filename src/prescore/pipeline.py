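"""End-to-end orchestration: simulate or load cohorts, impute, fit,
score overall and within subgroups, and compare predicted with observed
treatment effects.

The report is deterministic given the configured seeds (re-running with
the same configuration writes byte-identical output) and every number in
it is traceable to a seed and a config echo.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    CohortConfig,
    ImputationConfig,
    MissingnessConfig,
    OutcomeConfig,
    ScoreConfig,
)
from .cohorts import generate_background, generate_trial, inject_missingness
from .imputation import impute_pmm
from .markers import EffectProfile, MarkerSpec
from .score import PREResult, compute_pre_rrr, observed_rrr, single_marker_rrr
from .survival import RiskModel, fit_risk_model

logger = logging.getLogger("prescore")

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Marker change table
# ---------------------------------------------------------------------------

def marker_change_table(
    trial: pd.DataFrame,
    marker_specs: dict[str, MarkerSpec] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-marker arm mean changes and placebo-corrected differences.

    Changes for log-scale markers (UACR) are computed on the log scale
    and additionally reported as a percent change on the natural scale
    (``pct_change`` column, negative = reduction).  The CI and two-sided
    p-value for the placebo-corrected difference use the normal
    approximation for a difference of independent arm means.
    """
    arms = set(trial["arm"].unique())
    if arms != {"treated", "placebo"}:
        raise ValueError(f"need both arms, found {sorted(arms)}")
    if marker_specs is None:
        names = [
            c[: -len("_base")]
            for c in trial.columns
            if c.endswith("_base") and f"{c[:-5]}_m6" in trial.columns
        ]
        log_markers = {"uacr"}
        units = {m: "" for m in names}
    else:
        names = [m for m in marker_specs if f"{m}_base" in trial.columns]
        log_markers = {m for m, s in marker_specs.items() if s.family == "lognormal"}
        units = {m: marker_specs[m].unit for m in names}

    z = stats.norm.ppf(1 - (1 - level) / 2)
    rows = []
    for m in names:
        on_log = m in log_markers
        stats_by_arm = {}
        for arm in ("placebo", "treated"):
            sub = trial[trial["arm"] == arm]
            base = sub[f"{m}_base"].to_numpy(dtype=float)
            m6 = sub[f"{m}_m6"].to_numpy(dtype=float)
            chg = (np.log(m6) - np.log(base)) if on_log else (m6 - base)
            chg = chg[~np.isnan(chg)]
            stats_by_arm[arm] = (chg.mean(), chg.var(ddof=1) / len(chg), len(chg))
        (mp, vp, n_p), (mt, vt, n_t) = stats_by_arm["placebo"], stats_by_arm["treated"]
        diff = mt - mp
        se = np.sqrt(vp + vt)
        pval = 2 * stats.norm.sf(abs(diff) / se) if se > 0 else (0.0 if diff else 1.0)
        row = {
            "marker": m,
            "unit": "log-ratio" if on_log else units[m],
            "n_treated": n_t,
            "n_placebo": n_p,
            "placebo_change": mp,
            "treated_change": mt,
            "difference": diff,
            "ci_low": diff - z * se,
            "ci_high": diff + z * se,
            "p_value": pval,
            "pct_change": 100.0 * (np.exp(diff) - 1.0) if on_log else np.nan,
        }
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupFilter:
    """Named predicate over baseline fields of a trial table."""

    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]

    def mask(self, table: pd.DataFrame) -> pd.Series:
        m = self.predicate(table)
        if m.dtype != bool:
            raise ValueError(f"subgroup {self.name!r} predicate must return booleans")
        return m


def uacr_at_least(threshold: float = 30.0) -> SubgroupFilter:
    return SubgroupFilter(
        f"uacr_ge_{threshold:g}", lambda t: t["uacr_base"] >= threshold
    )


def uacr_below(threshold: float = 30.0) -> SubgroupFilter:
    return SubgroupFilter(
        f"uacr_lt_{threshold:g}", lambda t: t["uacr_base"] < threshold
    )


def empa_kidney_like(
    egfr_low: float = 20.0,
    egfr_mid: float = 45.0,
    egfr_high: float = 90.0,
    uacr_floor: float = 200.0,
) -> SubgroupFilter:
    """CKD-trial-style inclusion: eGFR 20-45, or eGFR 45-90 with
    UACR >= 200 mg/g."""
    def pred(t: pd.DataFrame) -> pd.Series:
        e = t["egfr_base"]
        low_egfr = (e >= egfr_low) & (e < egfr_mid)
        mid_egfr = (e >= egfr_mid) & (e < egfr_high) & (t["uacr_base"] >= uacr_floor)
        return low_egfr | mid_egfr

    return SubgroupFilter("empa_kidney_like", pred)


def apply_subgroup(table: pd.DataFrame, subgroup: SubgroupFilter) -> pd.DataFrame:
    """Rows satisfying the subgroup predicate; logs count and fraction."""
    mask = subgroup.mask(table)
    sub = table[mask]
    logger.info(
        "subgroup %s: %d/%d rows (%.1f%%)",
        subgroup.name, len(sub), len(table), 100 * len(sub) / max(len(table), 1),
    )
    if sub.empty:
        logger.warning("subgroup %s is empty", subgroup.name)
    return sub


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs.

    Cohorts come either from tables (``background``/``trial``) or from
    simulation configs.  ``outcomes`` lists endpoint truths used both to
    simulate and to name the endpoints being analysed.
    """

    markers: list[str]
    outcomes: list[OutcomeConfig]
    background: pd.DataFrame | None = None
    trial: pd.DataFrame | None = None
    background_config: CohortConfig | None = None
    trial_config: CohortConfig | None = None
    effects: EffectProfile | None = None
    missingness: MissingnessConfig | None = None
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    subgroups: list[SubgroupFilter] = field(default_factory=list)
    single_markers: bool = True
    ties: str = "efron"
    horizon: float | None = None
    harm_directions: dict[str, int] = field(default_factory=dict)
    seed: int = 0


def _pooled_score(
    model: RiskModel, tables: list[pd.DataFrame], config: ScoreConfig
) -> PREResult:
    """Score each completed dataset; pool the point and CI bounds by
    averaging (single-table input passes straight through)."""
    results = [compute_pre_rrr(model, t, config) for t in tables]
    if len(results) == 1:
        return results[0]
    first = results[0]
    return PREResult(
        rrr=float(np.mean([r.rrr for r in results])),
        ci_low=float(np.mean([r.ci_low for r in results])),
        ci_high=float(np.mean([r.ci_high for r in results])),
        form=first.form,
        n_draws=first.n_draws,
        seed=first.seed,
        n_treated=first.n_treated,
        n_placebo=first.n_placebo,
        level=first.level,
        horizon=first.horizon,
    )


def _result_dict(r: PREResult) -> dict:
    return {
        "rrr": r.rrr,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "form": r.form,
        "n_draws": r.n_draws,
        "n_treated": r.n_treated,
        "n_placebo": r.n_placebo,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the report as a plain dict.

    Stages: simulate/load -> inject+impute missingness (if configured)
    -> fit a risk model per endpoint on the background cohort -> score
    the trial overall, per subgroup and per single marker -> observed
    RRR where outcome columns exist.
    """
    stage = "inputs"
    try:
        background = config.background
        if background is None:
            stage = "simulate-background"
            if config.background_config is None:
                raise ValueError("neither background table nor config provided")
            background = generate_background(config.background_config, config.outcomes)
        trial = config.trial
        if trial is None:
            stage = "simulate-trial"
            if config.trial_config is None or config.effects is None:
                raise ValueError("neither trial table nor (config, effects) provided")
            trial = generate_trial(config.trial_config, config.effects, config.outcomes)
            if config.missingness is not None:
                trial = inject_missingness(trial, config.missingness, seed=config.seed)

        stage = "impute"
        marker_cols = [f"{m}_base" for m in config.markers] + [
            f"{m}_m6" for m in config.markers
        ]
        has_blanks = trial[[c for c in marker_cols if c in trial.columns]].isna().any().any()
        if has_blanks:
            completed = impute_pmm(trial, config.imputation)
        else:
            completed = [trial]

        report: dict = {
            "schema_version": SCHEMA_VERSION,
            "seed": config.seed,
            "markers": config.markers,
            "n_background": len(background),
            "n_trial": len(trial),
            "n_imputations": len(completed) if has_blanks else 0,
            "score_config": {
                "form": config.score.rrr_form,
                "n_draws": config.score.n_draws,
                "level": config.score.level,
                "seed": config.score.seed,
            },
            "endpoints": {},
        }

        stage = "marker-change-table"
        specs = (
            config.trial_config.marker_specs if config.trial_config is not None else None
        )
        report["marker_changes"] = marker_change_table(completed[0], specs).to_dict(
            orient="records"
        )

        for outcome in config.outcomes:
            stage = f"fit-{outcome.name}"
            model = fit_risk_model(
                background,
                outcome.name,
                config.markers,
                ties=config.ties,
                horizon=config.horizon,
                harm_directions=config.harm_directions,
            )
            ep_report: dict = {
                "horizon": model.horizon,
                "n_events_background": model.fit.n_events,
                "coefficients": dict(zip(model.markers, model.fit.beta.tolist())),
                "standard_errors": dict(zip(model.markers, model.fit.se.tolist())),
                "subgroups": {},
            }

            groups: list[tuple[str, list[pd.DataFrame]]] = [("overall", completed)]
            for sg in config.subgroups:
                stage = f"subgroup-{sg.name}"
                tabs = [apply_subgroup(t, sg) for t in completed]
                groups.append((sg.name, tabs))

            for gname, tabs in groups:
                stage = f"score-{outcome.name}-{gname}"
                if tabs[0].empty:
                    ep_report["subgroups"][gname] = {"n": 0, "note": "empty subgroup"}
                    continue
                sg_entry: dict = {
                    "n": len(tabs[0]),
                    "predicted": _result_dict(
                        _pooled_score(model, tabs, config.score)
                    ),
                }
                if config.single_markers:
                    sg_entry["single_marker_rrr"] = {
                        m: float(np.mean([
                            single_marker_rrr(model, t, m, config.score).rrr
                            for t in tabs
                        ]))
                        for m in config.markers
                    }
                tcol = f"time_{outcome.name}"
                if tcol in tabs[0].columns:
                    ev = tabs[0][f"event_{outcome.name}"]
                    sg_entry["n_events_trial"] = int(ev.sum())
                    try:
                        obs, lo, hi = observed_rrr(tabs[0], outcome.name)
                        sg_entry["observed"] = {"rrr": obs, "ci_low": lo, "ci_high": hi}
                    except ValueError as exc:
                        sg_entry["observed"] = {"error": str(exc)}
                ep_report["subgroups"][gname] = sg_entry

            report["endpoints"][outcome.name] = ep_report
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def write_report(report: dict, out_dir) -> Path:
    """Write the JSON report (and a flat CSV of scores) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    rows = []
    for ep, ep_rep in report.get("endpoints", {}).items():
        for sg, entry in ep_rep.get("subgroups", {}).items():
            if "predicted" in entry:
                row = {"endpoint": ep, "subgroup": sg, "n": entry["n"]}
                row.update({f"pred_{k}": v for k, v in entry["predicted"].items()})
                if "observed" in entry and "rrr" in entry["observed"]:
                    row.update({f"obs_{k}": v for k, v in entry["observed"].items()})
                rows.append(row)
    if rows:
        pd.DataFrame(rows).to_csv(out / "scores.csv", index=False)
    return path
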