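"""Configuration types for cohort simulation, imputation and scoring.

All configs are plain dataclasses that validate on construction and can
be round-tripped through YAML (see :func:`load_config_bundle`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markers import (
    EffectProfile,
    MarkerEffect,
    MarkerSpec,
    background_marker_specs,
    calibrated_effect_profile,
    trial_marker_specs,
)

#: default correlation among the metabolic block on the transformed scale
DEFAULT_BLOCK_CORRELATION = 0.2

#: default follow-up / administrative censoring horizon (years)
DEFAULT_FOLLOWUP_YEARS = 3.1


def default_correlation(markers: list[str], rho: float = DEFAULT_BLOCK_CORRELATION) -> np.ndarray:
    """Equicorrelated block (off-diagonal ``rho``) with unit diagonal."""
    p = len(markers)
    corr = np.full((p, p), rho)
    np.fill_diagonal(corr, 1.0)
    return corr


def _check_correlation(corr: np.ndarray, p: int) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (p, p):
        raise ValueError(f"correlation must be {p}x{p}, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semidefinite (min eigenvalue {eigmin:.3g})"
        )
    return corr


@dataclass
class CohortConfig:
    """Size, allocation and baseline marker structure of a cohort."""

    n: int
    marker_specs: dict[str, MarkerSpec]
    allocation_ratio: tuple[int, int] = (2, 1)  # treated : placebo
    correlation: np.ndarray | None = None
    seed: int = 0
    # descriptive covariates (not scored): age, sex, eGFR
    demographics: dict[str, float] = field(default_factory=lambda: {
        "age_mean": 63.1, "age_sd": 8.7,
        "female_frac": 0.285,
        "egfr_mean": 74.0, "egfr_sd": 21.4,
    })

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size n must be > 0")
        if min(self.allocation_ratio) <= 0:
            raise ValueError("allocation ratio parts must be positive")
        names = list(self.marker_specs)
        if self.correlation is None:
            self.correlation = default_correlation(names)
        self.correlation = _check_correlation(self.correlation, len(names))

    @property
    def marker_names(self) -> list[str]:
        return list(self.marker_specs)


@dataclass
class OutcomeConfig:
    """Generator-side truth for one time-to-event endpoint.

    ``coefficients`` maps marker name to the true log-hazard-ratio per
    unit of the *transformed* marker (log scale for UACR).
    ``direct_log_hr`` is an additional treated-arm log hazard ratio not
    mediated by any marker; nonzero values emulate treatments whose
    benefit is only partly captured by the measured markers.
    """

    name: str
    coefficients: dict[str, float]
    baseline_hazard: float = 0.05
    censoring_years: float = DEFAULT_FOLLOWUP_YEARS
    random_censoring_rate: float = 0.0
    direct_log_hr: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")
        if self.censoring_years <= 0:
            raise ValueError("censoring time must be > 0")
        if self.random_censoring_rate < 0:
            raise ValueError("random censoring rate must be >= 0")


@dataclass
class MissingnessConfig:
    """Mechanism and per-marker rates for blanking marker values."""

    mechanism: str = "MCAR"
    proportions: dict[str, float] = field(default_factory=dict)
    mar_covariate: str | None = None
    mar_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError("mechanism must be MCAR or MAR")
        for col, p in self.proportions.items():
            if not 0 <= p < 1:
                raise ValueError(f"missing proportion for {col} must be in [0, 1)")
        if self.mechanism == "MAR" and self.mar_covariate is None:
            raise ValueError("MAR mechanism requires mar_covariate")


@dataclass
class ImputationConfig:
    """Chained-equation PMM settings: ``m`` completed datasets, ``k`` donors."""

    m: int = 5
    k: int = 5
    n_iter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.k < 1 or self.n_iter < 1:
            raise ValueError("m, k and n_iter must all be >= 1")


@dataclass
class ScoreConfig:
    """Scoring options: horizon, resampling draws, CI level, RRR form."""

    horizon: float | None = None  # None -> the model's default horizon
    n_draws: int = 100
    level: float = 0.95
    seed: int = 0
    rrr_form: str = "ratio_of_ratios"

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if not 0 < self.level < 1:
            raise ValueError("CI level must be in (0, 1)")
        if self.rrr_form not in ("ratio_of_ratios", "adjusted_difference"):
            raise ValueError(f"unknown rrr_form {self.rrr_form!r}")


# ---------------------------------------------------------------------------
# Default generator truths
# ---------------------------------------------------------------------------

def default_cv_outcome() -> OutcomeConfig:
    """CV composite endpoint truth: blood pressure, lipids and glycemia
    dominate; albuminuria contributes moderately."""
    return OutcomeConfig(
        name="cv",
        coefficients={
            "hba1c": 0.08,
            "sbp": 0.012,
            "uacr": 0.15,       # per unit log-UACR
            "hemoglobin": -0.008,
            "weight": 0.004,
            "hdl": -0.5,
            "ldl": 0.15,
            "uric_acid": 0.0015,
            "potassium": 0.10,
        },
        baseline_hazard=0.04,
    )


def default_kidney_outcome() -> OutcomeConfig:
    """Kidney composite endpoint truth: albuminuria is the dominant
    predictor, with glycemia, blood pressure and hemoglobin secondary."""
    return OutcomeConfig(
        name="kidney",
        coefficients={
            "hba1c": 0.10,
            "sbp": 0.010,
            "uacr": 0.40,       # per unit log-UACR
            "hemoglobin": -0.015,
            "weight": 0.005,
            "hdl": -0.30,
            "ldl": 0.05,
            "uric_acid": 0.002,
            "potassium": 0.15,
        },
        baseline_hazard=0.055,
    )


def default_background_config(n: int = 6355, seed: int = 0) -> CohortConfig:
    return CohortConfig(
        n=n,
        marker_specs=background_marker_specs(),
        seed=seed,
        demographics={
            "age_mean": 61.0, "age_sd": 9.0,
            "female_frac": 0.335,
            "egfr_mean": 49.8, "egfr_sd": 23.3,
        },
    )


def default_trial_config(n: int = 7020, seed: int = 0) -> CohortConfig:
    return CohortConfig(n=n, marker_specs=trial_marker_specs(), seed=seed)


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def _effect_to_dict(e: MarkerEffect) -> dict:
    d = {"placebo_drift": e.placebo_drift, "change_sd": e.change_sd}
    if e.treated_extra_pct is not None:
        d["treated_extra_pct"] = e.treated_extra_pct
    else:
        d["treated_extra"] = e.treated_extra
    return d


def dump_config_bundle(
    path,
    cohort: CohortConfig,
    effects: EffectProfile | None = None,
    outcomes: list[OutcomeConfig] | None = None,
) -> None:
    """Write a cohort/effects/outcomes bundle as YAML."""
    import yaml

    doc: dict = {
        "cohort": {
            "n": cohort.n,
            "allocation_ratio": list(cohort.allocation_ratio),
            "seed": cohort.seed,
            "correlation": np.asarray(cohort.correlation).tolist(),
            "markers": {
                name: {
                    "unit": s.unit,
                    "family": s.family,
                    "location": s.location,
                    "scale": s.scale,
                    "harm_direction": s.harm_direction,
                }
                for name, s in cohort.marker_specs.items()
            },
        }
    }
    if effects is not None:
        doc["effects"] = {m: _effect_to_dict(e) for m, e in effects.effects.items()}
    if outcomes:
        doc["outcomes"] = [
            {
                "name": o.name,
                "coefficients": o.coefficients,
                "baseline_hazard": o.baseline_hazard,
                "censoring_years": o.censoring_years,
                "random_censoring_rate": o.random_censoring_rate,
                "direct_log_hr": o.direct_log_hr,
            }
            for o in outcomes
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config_bundle(path) -> dict:
    """Load a YAML bundle into config objects.

    Returns a dict with keys ``cohort`` (CohortConfig), optionally
    ``effects`` (EffectProfile) and ``outcomes`` (list of OutcomeConfig).
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)

    c = doc["cohort"]
    specs = {
        name: MarkerSpec(
            name=name,
            unit=s["unit"],
            family=s["family"],
            location=float(s["location"]),
            scale=float(s["scale"]),
            harm_direction=int(s.get("harm_direction", 1)),
        )
        for name, s in c["markers"].items()
    }
    corr = np.asarray(c["correlation"], dtype=float) if "correlation" in c else None
    out: dict = {
        "cohort": CohortConfig(
            n=int(c["n"]),
            marker_specs=specs,
            allocation_ratio=tuple(c.get("allocation_ratio", (2, 1))),
            correlation=corr,
            seed=int(c.get("seed", 0)),
        )
    }
    if "effects" in doc:
        out["effects"] = EffectProfile({
            m: MarkerEffect(
                placebo_drift=float(e.get("placebo_drift", 0.0)),
                treated_extra=float(e.get("treated_extra", 0.0)),
                treated_extra_pct=(
                    float(e["treated_extra_pct"]) if "treated_extra_pct" in e else None
                ),
                change_sd=float(e.get("change_sd", 1.0)),
            )
            for m, e in doc["effects"].items()
        })
    if "outcomes" in doc:
        out["outcomes"] = [
            OutcomeConfig(
                name=o["name"],
                coefficients={k: float(v) for k, v in o["coefficients"].items()},
                baseline_hazard=float(o.get("baseline_hazard", 0.05)),
                censoring_years=float(o.get("censoring_years", DEFAULT_FOLLOWUP_YEARS)),
                random_censoring_rate=float(o.get("random_censoring_rate", 0.0)),
                direct_log_hr=float(o.get("direct_log_hr", 0.0)),
            )
            for o in doc["outcomes"]
        ]
    return out


__all__ = [
    "CohortConfig",
    "OutcomeConfig",
    "MissingnessConfig",
    "ImputationConfig",
    "ScoreConfig",
    "default_correlation",
    "default_cv_outcome",
    "default_kidney_outcome",
    "default_background_config",
    "default_trial_config",
    "calibrated_effect_profile",
    "dump_config_bundle",
    "load_config_bundle",
    "DEFAULT_FOLLOWUP_YEARS",
]
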