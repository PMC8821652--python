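"""The PRE (Parameter Response Efficacy) score.

The score translates short-term (baseline to month 6) changes in
multiple risk markers, observed in a two-arm trial, into a predicted
long-term relative risk reduction (RRR).  Each patient's absolute risk
at the model horizon is evaluated from a Cox risk model fitted on an
independent background cohort, at both timepoints and in both arms; the
treated arm's risk change relative to the placebo arm's risk change is
the predicted treatment effect:

    ratio_of_ratios:      RRR = 100 * (1 - [rT(m6)/rT(base)] / [rP(m6)/rP(base)])
    adjusted_difference:  RRR = 100 * (-[(rT(m6)-rT(base)) - (rP(m6)-rP(base))] / rT(base))

where ``r_a(tp)`` is the mean predicted risk in arm ``a`` at timepoint
``tp``.  The two forms agree to first order when risks are small.

Confidence intervals resample the Cox coefficients: each draw replaces
``beta_l`` with an independent Normal(beta_l, SE_l^2) variate (the
coefficient covariance is deliberately ignored), recomputes the RRR,
and the interval is the percentile band over the draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScoreConfig
from .survival import RiskModel, SurvivalDataset, fit_cox

ARMS = ("treated", "placebo")


@dataclass
class PREResult:
    """Predicted RRR (percent) with its resampling CI and provenance."""

    rrr: float
    ci_low: float
    ci_high: float
    form: str
    n_draws: int
    seed: int
    n_treated: int
    n_placebo: int
    level: float = 0.95
    horizon: float = float("nan")
    per_marker: dict[str, float] = field(default_factory=dict)
    point_outside_ci: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RRR {self.rrr:.1f}% ({self.level*100:.0f}% CI "
            f"{self.ci_low:.1f} to {self.ci_high:.1f}), form={self.form}"
        )


def _arm_markers(trial: pd.DataFrame, arm: str, markers: list[str], timepoint: str) -> pd.DataFrame:
    if timepoint not in ("baseline", "month6"):
        raise ValueError("timepoint must be 'baseline' or 'month6'")
    suffix = "_base" if timepoint == "baseline" else "_m6"
    sub = trial[trial["arm"] == arm]
    if sub.empty:
        raise ValueError(f"arm {arm!r} is empty")
    raw = sub[[f"{m}{suffix}" for m in markers]].copy()
    raw.columns = markers
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()].tolist()
        raise ValueError(
            f"missing marker values at {timepoint} in arm {arm}: {', '.join(bad)} "
            "(impute before scoring)"
        )
    return raw


def mean_arm_risk(
    model: RiskModel,
    trial: pd.DataFrame,
    arm: str,
    timepoint: str,
    beta_override: np.ndarray | None = None,
) -> float:
    """Mean predicted absolute risk over one arm at one timepoint."""
    raw = _arm_markers(trial, arm, model.markers, timepoint)
    return float(model.predict_risk(raw, beta_override=beta_override).mean())


def _rrr_from_risks(rt_b: float, rt_m: float, rp_b: float, rp_m: float, form: str) -> float:
    if min(rt_b, rp_b) <= 0:
        raise ValueError("zero baseline risk; RRR undefined")
    if form == "ratio_of_ratios":
        return 100.0 * (1.0 - (rt_m / rt_b) / (rp_m / rp_b))
    return 100.0 * (-((rt_m - rt_b) - (rp_m - rp_b)) / rt_b)


def _point_rrr(
    model: RiskModel,
    trial: pd.DataFrame,
    form: str,
    beta_override: np.ndarray | None = None,
) -> float:
    risks = {
        (arm, tp): mean_arm_risk(model, trial, arm, tp, beta_override)
        for arm in ARMS
        for tp in ("baseline", "month6")
    }
    return _rrr_from_risks(
        risks[("treated", "baseline")],
        risks[("treated", "month6")],
        risks[("placebo", "baseline")],
        risks[("placebo", "month6")],
        form,
    )


def ci_resample(
    model: RiskModel, trial: pd.DataFrame, config: ScoreConfig
) -> tuple[float, float, np.ndarray]:
    """Percentile CI of the RRR over coefficient-resampling draws.

    Returns ``(low, high, draws)``.  Each coefficient is drawn
    independently from Normal(beta_hat, SE^2); the baseline survival is
    held fixed.
    """
    beta = model.fit.beta.to_numpy()
    se = model.fit.se.to_numpy()
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, zlib.crc32(b"ci-resample")])
    draws = np.empty(config.n_draws)
    for d in range(config.n_draws):
        b = beta + se * rng.standard_normal(beta.shape[0])
        draws[d] = _point_rrr(model, trial, config.rrr_form, beta_override=b)
    alpha = (1.0 - config.level) / 2.0
    low, high = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return float(low), float(high), draws


def compute_pre_rrr(
    model: RiskModel, trial: pd.DataFrame, config: ScoreConfig | None = None
) -> PREResult:
    """Compute the PRE score for a two-arm trial table.

    The trial table needs ``arm`` plus complete ``<marker>_base`` and
    ``<marker>_m6`` columns for every model marker.
    """
    config = config or ScoreConfig()
    point = _point_rrr(model, trial, config.rrr_form)
    low, high, _ = ci_resample(model, trial, config)
    n_t = int((trial["arm"] == "treated").sum())
    n_p = int((trial["arm"] == "placebo").sum())
    return PREResult(
        rrr=point,
        ci_low=low,
        ci_high=high,
        form=config.rrr_form,
        n_draws=config.n_draws,
        seed=config.seed,
        n_treated=n_t,
        n_placebo=n_p,
        level=config.level,
        horizon=model.horizon,
        point_outside_ci=not (low <= point <= high),
    )


def single_marker_rrr(
    model: RiskModel,
    trial: pd.DataFrame,
    marker: str,
    config: ScoreConfig | None = None,
) -> PREResult:
    """PRE score attributable to one marker's observed change.

    The month-6 marker vector is the baseline vector with only the
    chosen marker advanced to its observed month-6 value; the full
    multivariable coefficient vector is reused.
    """
    if marker not in model.markers:
        raise KeyError(f"marker {marker!r} not in model ({', '.join(model.markers)})")
    mod = trial.copy()
    for m in model.markers:
        if m != marker:
            mod[f"{m}_m6"] = mod[f"{m}_base"]
    return compute_pre_rrr(model, mod, config)


def observed_rrr(
    trial: pd.DataFrame, endpoint: str, level: float = 0.95
) -> tuple[float, float, float]:
    """Observed RRR from a treatment-arm Cox model: 100 * (1 - HR).

    Returns ``(rrr, ci_low, ci_high)`` with a Wald interval transformed
    from the log-hazard-ratio scale.
    """
    tcol, ecol = f"time_{endpoint}", f"event_{endpoint}"
    if tcol not in trial.columns or ecol not in trial.columns:
        raise KeyError(f"trial table lacks outcome columns for endpoint {endpoint!r}")
    for arm in ARMS:
        sub = trial[trial["arm"] == arm]
        if sub.empty:
            raise ValueError(f"arm {arm!r} is empty")
        if sub[ecol].sum() == 0:
            raise ValueError(f"zero events in arm {arm!r}; hazard ratio undefined")
    X = pd.DataFrame({"treated": (trial["arm"] == "treated").astype(float).to_numpy()})
    data = SurvivalDataset(X=X, time=trial[tcol].to_numpy(), event=trial[ecol].to_numpy())
    fit = fit_cox(data)
    b = float(fit.beta.iloc[0])
    se = float(fit.se.iloc[0])
    z = stats.norm.ppf(1 - (1 - level) / 2)
    rrr = 100.0 * (1.0 - np.exp(b))
    low = 100.0 * (1.0 - np.exp(b + z * se))
    high = 100.0 * (1.0 - np.exp(b - z * se))
    return rrr, low, high
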