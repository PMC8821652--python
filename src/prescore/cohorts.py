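"""Synthetic cohort generation with marker-mediated survival outcomes.

Two kinds of cohorts are generated:

* a *background* cohort — baseline markers plus time-to-event outcomes
  whose hazards depend on the baseline markers through a known
  coefficient vector; used to fit the Cox risk models, and
* a two-arm *trial* cohort — baseline and month-6 markers, where the
  month-6 values carry the treatment effect and the outcome hazards
  depend on the month-6 (post-treatment) values, so that the simulated
  treatment effect is wholly mediated by the measured markers.  An
  optional ``direct_log_hr`` adds a non-mediated treated-arm hazard
  effect to emulate treatments whose benefit the markers under-explain.

Baseline markers are drawn through a Gaussian copula: correlated
standard normals are mapped to each marker's marginal (normal, or
log-normal for UACR).  Event times are exponential given the linear
predictor and rounded up to whole days, which produces the tied event
times a real trial database would contain.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .config import CohortConfig, MissingnessConfig, OutcomeConfig
from .markers import EffectProfile

DAY = 1.0 / 365.25


def _rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-operation RNG sub-stream."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def _draw_baseline(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    names = config.marker_names
    chol = np.linalg.cholesky(
        np.asarray(config.correlation) + 1e-12 * np.eye(len(names))
    )
    z = rng.standard_normal((config.n, len(names))) @ chol.T
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        spec = config.marker_specs[name]
        v = spec.location + spec.scale * z[:, j]
        if spec.family == "lognormal":
            v = np.exp(v)
        cols[f"{name}_base"] = v
    demo = config.demographics
    frame = pd.DataFrame({
        "id": np.arange(1, config.n + 1),
        "age": np.round(demo["age_mean"] + demo["age_sd"] * rng.standard_normal(config.n), 1),
        "sex": (rng.random(config.n) < demo["female_frac"]).astype(int),
        "egfr_base": np.clip(
            demo["egfr_mean"] + demo["egfr_sd"] * rng.standard_normal(config.n), 5.0, None
        ),
    })
    return pd.concat([frame, pd.DataFrame(cols)], axis=1)


def _transformed(table: pd.DataFrame, markers: list[str], specs, suffix: str) -> np.ndarray:
    """Marker matrix on the modelling scale (log for log-normal markers)."""
    cols = []
    for name in markers:
        v = table[f"{name}{suffix}"].to_numpy(dtype=float)
        if specs[name].family == "lognormal":
            v = np.log(v)
        cols.append(v)
    return np.column_stack(cols)


def _linear_predictor(
    table: pd.DataFrame,
    config: CohortConfig,
    outcome: OutcomeConfig,
    suffix: str,
) -> np.ndarray:
    """True log hazard ratio relative to a population-mean subject."""
    unknown = [m for m in outcome.coefficients if m not in config.marker_specs]
    if unknown:
        raise KeyError(f"outcome coefficients name unknown marker(s): {', '.join(unknown)}")
    markers = list(outcome.coefficients)
    x = _transformed(table, markers, config.marker_specs, suffix)
    ref = np.array([config.marker_specs[m].location for m in markers])
    beta = np.array([outcome.coefficients[m] for m in markers])
    return (x - ref) @ beta


def _simulate_event(
    rate: np.ndarray, outcome: OutcomeConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = rate.shape[0]
    t_event = rng.exponential(1.0 / rate)
    t_cens = np.full(n, outcome.censoring_years)
    if outcome.random_censoring_rate > 0:
        t_cens = np.minimum(
            t_cens, rng.exponential(1.0 / outcome.random_censoring_rate, size=n)
        )
    event = (t_event <= t_cens).astype(int)
    time = np.where(event == 1, t_event, t_cens)
    # day granularity, as in a real trial database; introduces ties
    time = np.maximum(np.ceil(time / DAY) * DAY, DAY)
    return np.round(time, 10), event


def generate_background(
    config: CohortConfig, outcomes: OutcomeConfig | list[OutcomeConfig]
) -> pd.DataFrame:
    """Generate a background cohort with baseline-marker-driven outcomes.

    Event times for each endpoint are exponential with rate
    ``lambda0 * exp(beta* . (x - mean))`` evaluated at the baseline
    covariates, administratively censored at ``censoring_years``.
    Reproducible given ``config.seed``.
    """
    if isinstance(outcomes, OutcomeConfig):
        outcomes = [outcomes]
    table = _draw_baseline(config, _rng(config.seed, "background-baseline"))
    for outcome in outcomes:
        lp = _linear_predictor(table, config, outcome, "_base")
        rate = outcome.baseline_hazard * np.exp(lp)
        time, event = _simulate_event(
            rate, outcome, _rng(config.seed, f"background-outcome-{outcome.name}")
        )
        table[f"time_{outcome.name}"] = time
        table[f"event_{outcome.name}"] = event
    return table


def _assign_arms(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    a, b = config.allocation_ratio
    n_treated = int(round(config.n * a / (a + b)))
    arm = np.array(["treated"] * n_treated + ["placebo"] * (config.n - n_treated))
    rng.shuffle(arm)
    return arm


def generate_trial(
    config: CohortConfig,
    effects: EffectProfile,
    outcomes: OutcomeConfig | list[OutcomeConfig] | None = None,
) -> pd.DataFrame:
    """Generate a two-arm trial with baseline and month-6 markers.

    Month-6 value = baseline + placebo drift + (treated) effect + noise,
    all applied on the modelling scale (log for UACR, where the treated
    effect is a percent change on the natural scale).  When outcomes are
    requested their hazards are computed from the month-6 markers, so
    the treatment effect is transmitted only through the markers, apart
    from any configured ``direct_log_hr``.
    """
    effects.validate_against(config.marker_specs)
    if isinstance(outcomes, OutcomeConfig):
        outcomes = [outcomes]
    table = _draw_baseline(config, _rng(config.seed, "trial-baseline"))
    arm = _assign_arms(config, _rng(config.seed, "trial-arms"))
    table.insert(1, "arm", arm)
    treated = (arm == "treated").astype(float)

    rng_chg = _rng(config.seed, "trial-changes")
    for name in config.marker_names:
        spec = config.marker_specs[name]
        eff = effects[name] if name in effects else None
        base = table[f"{name}_base"].to_numpy(dtype=float)
        on_log = spec.family == "lognormal"
        x = np.log(base) if on_log else base
        if eff is not None:
            change = (
                eff.placebo_drift
                + treated * eff.log_scale_effect
                + eff.change_sd * rng_chg.standard_normal(config.n)
            )
        else:
            change = np.zeros(config.n)
        m6 = x + change
        table[f"{name}_m6"] = np.exp(m6) if on_log else m6

    for outcome in outcomes or []:
        lp = _linear_predictor(table, config, outcome, "_m6")
        lp = lp + outcome.direct_log_hr * treated
        rate = outcome.baseline_hazard * np.exp(lp)
        time, event = _simulate_event(
            rate, outcome, _rng(config.seed, f"trial-outcome-{outcome.name}")
        )
        table[f"time_{outcome.name}"] = time
        table[f"event_{outcome.name}"] = event
    return table


def calibrate_baseline_hazard(
    config: CohortConfig,
    outcome: OutcomeConfig,
    target_event_fraction: float,
    n_calib: int = 50_000,
    seed: int = 12345,
) -> OutcomeConfig:
    """Return a copy of ``outcome`` with ``baseline_hazard`` chosen so the
    expected event fraction under administrative censoring matches the
    target.

    Solves ``E[1 - exp(-lambda0 * exp(lp) * C)] = target`` by bisection
    over a Monte-Carlo draw of baseline linear predictors.
    """
    if not 0 < target_event_fraction < 1:
        raise ValueError("target event fraction must be in (0, 1)")
    calib_cfg = CohortConfig(
        n=n_calib,
        marker_specs=config.marker_specs,
        allocation_ratio=config.allocation_ratio,
        correlation=np.asarray(config.correlation).copy(),
        seed=seed,
        demographics=dict(config.demographics),
    )
    table = _draw_baseline(calib_cfg, _rng(seed, "calibration-baseline"))
    lp = _linear_predictor(table, calib_cfg, outcome, "_base")
    rel = np.exp(lp)
    horizon = outcome.censoring_years

    def frac(lam: float) -> float:
        return float(np.mean(1.0 - np.exp(-lam * rel * horizon)))

    lo, hi = 1e-8, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target_event_fraction:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    return OutcomeConfig(
        name=outcome.name,
        coefficients=dict(outcome.coefficients),
        baseline_hazard=lam,
        censoring_years=outcome.censoring_years,
        random_censoring_rate=outcome.random_censoring_rate,
        direct_log_hr=outcome.direct_log_hr,
    )


def true_rrr(
    outcome: OutcomeConfig,
    effects: EffectProfile,
    horizon: float,
    config: CohortConfig,
    n_sim: int = 200_000,
    seed: int = 2024,
) -> float:
    """Monte-Carlo oracle for the generator's true RRR (percent).

    Simulates a large trial's month-6 markers and evaluates each
    subject's exact event probability by ``horizon`` under the
    exponential hazard, then returns ``100 * (1 - risk_T / risk_P)``.
    No event times are simulated, so the only noise is marker sampling.
    """
    # administrative censoring is day-rounded upward in the generator
    cens = np.ceil(outcome.censoring_years / DAY) * DAY
    if horizon > cens + 1e-9:
        raise ValueError(
            f"horizon {horizon} exceeds censoring time {outcome.censoring_years}"
        )
    sim_cfg = CohortConfig(
        n=n_sim,
        marker_specs=config.marker_specs,
        allocation_ratio=(1, 1),
        correlation=np.asarray(config.correlation).copy(),
        seed=seed,
        demographics=dict(config.demographics),
    )
    table = generate_trial(sim_cfg, effects)
    treated = (table["arm"] == "treated").to_numpy()
    lp = _linear_predictor(table, sim_cfg, outcome, "_m6")
    lp = lp + outcome.direct_log_hr * treated
    risk = 1.0 - np.exp(-outcome.baseline_hazard * np.exp(lp) * horizon)
    return 100.0 * (1.0 - risk[treated].mean() / risk[~treated].mean())


def inject_missingness(
    table: pd.DataFrame, mconfig: MissingnessConfig, seed: int = 0
) -> pd.DataFrame:
    """Blank marker values according to an MCAR or MAR mechanism.

    Only marker columns may be blanked; identifiers, arm and outcome
    columns are never touched.  Under MAR the per-record missingness
    probability varies with the (standardized) dependence covariate on
    the logit scale while preserving the target marginal rate
    approximately.
    """
    protected = {c for c in table.columns if c.startswith(("time_", "event_"))}
    protected |= {"id", "arm", "sex"}
    bad = [c for c in mconfig.proportions if c in protected]
    if bad:
        raise ValueError(f"cannot blank protected column(s): {', '.join(bad)}")
    missing_cols = [c for c in mconfig.proportions if c not in table.columns]
    if missing_cols:
        raise KeyError(f"column(s) not in table: {', '.join(missing_cols)}")

    out = table.copy()
    rng = _rng(seed, "missingness")
    if mconfig.mechanism == "MAR":
        if mconfig.mar_covariate not in table.columns:
            raise KeyError(
                f"MAR dependence covariate {mconfig.mar_covariate!r} not in table"
            )
        z = table[mconfig.mar_covariate].to_numpy(dtype=float)
        z = (z - z.mean()) / max(z.std(), 1e-12)
    for col, p in mconfig.proportions.items():
        if p == 0:
            continue
        if mconfig.mechanism == "MCAR":
            mask = rng.random(len(out)) < p
        else:
            logit = np.log(p / (1 - p)) + mconfig.mar_strength * z
            mask = rng.random(len(out)) < 1.0 / (1.0 + np.exp(-logit))
        out.loc[mask, col] = np.nan
    return out


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort as CSV, missing values as empty fields."""
    table.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
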