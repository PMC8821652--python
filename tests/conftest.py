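"""Shared fixtures: small-to-moderate synthetic cohorts and fitted models.

Session-scoped fixtures keep the expensive generation/fit work to one
pass; tests that need custom configurations build their own.
"""

import numpy as np
import pandas as pd
import pytest

import prescore as ps
from prescore.markers import MARKER_NAMES, MarkerSpec


def harm_directions() -> dict[str, int]:
    return {m: s.harm_direction for m, s in ps.trial_marker_specs().items()}


@pytest.fixture(scope="session")
def kidney_outcome() -> ps.OutcomeConfig:
    """Kidney endpoint truth, baseline hazard calibrated to a 17.8%
    background event fraction."""
    return ps.calibrate_baseline_hazard(
        ps.default_background_config(seed=101),
        ps.default_kidney_outcome(),
        0.178,
        n_calib=20_000,
    )


@pytest.fixture(scope="session")
def background(kidney_outcome) -> pd.DataFrame:
    return ps.generate_background(
        ps.default_background_config(n=4000, seed=101), kidney_outcome
    )


@pytest.fixture(scope="session")
def kidney_model(background) -> ps.RiskModel:
    return ps.fit_risk_model(
        background, "kidney", list(MARKER_NAMES), harm_directions=harm_directions()
    )


@pytest.fixture(scope="session")
def trial(kidney_outcome) -> pd.DataFrame:
    return ps.generate_trial(
        ps.default_trial_config(n=4000, seed=202),
        ps.calibrated_effect_profile(),
        kidney_outcome,
    )


@pytest.fixture()
def score_config() -> ps.ScoreConfig:
    return ps.ScoreConfig(n_draws=50, seed=7)


# ---------------------------------------------------------------------------
# A deliberately tiny single-marker world for closed-form checks
# ---------------------------------------------------------------------------

def single_marker_config(n: int, seed: int, sd: float = 1.0) -> ps.CohortConfig:
    return ps.CohortConfig(
        n=n,
        marker_specs={"x": MarkerSpec("x", "", "normal", 0.0, sd)},
        correlation=np.eye(1),
        seed=seed,
    )


@pytest.fixture(scope="session")
def rare_event_model():
    """Single-marker Cox model fitted in a rare-event regime
    (baseline survival above 0.995 at every horizon)."""
    outcome = ps.OutcomeConfig(
        name="rare", coefficients={"x": 0.3}, baseline_hazard=0.001, censoring_years=3.0
    )
    bg = ps.generate_background(single_marker_config(40_000, 303), outcome)
    model = ps.fit_risk_model(bg, "rare", ["x"])
    return model, outcome


def uniform_shift_trial(n: int, delta: float, seed: int) -> pd.DataFrame:
    """Two equal arms, x ~ N(0,1); treated month-6 = baseline + delta,
    placebo unchanged.  No noise, no drift."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    arm = np.array(["treated", "placebo"])[np.arange(n) % 2]
    return pd.DataFrame({
        "id": np.arange(n),
        "arm": arm,
        "x_base": x,
        "x_m6": x + np.where(arm == "treated", delta, 0.0),
    })
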