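"""PRE scoring: arm risks, RRR forms, attribution, resampling CIs,
observed RRR."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import prescore as ps
from prescore.markers import MARKER_NAMES
from prescore.survival import StepSurvival

from conftest import uniform_shift_trial


def toy_model(beta=0.3, s0_T=0.99, se=0.1):
    fit = ps.CoxFit(
        beta=pd.Series([beta], index=["x"]),
        se=pd.Series([se], index=["x"]),
        covariance=pd.DataFrame([[se ** 2]], index=["x"], columns=["x"]),
        log_likelihood=0.0,
        ties="efron",
        centering_means=pd.Series([0.0], index=["x"]),
        n=100,
        n_events=50,
    )
    s0 = StepSurvival(knots=np.array([1.0]), values=np.array([s0_T]), t_max=2.0)
    return ps.RiskModel(fit=fit, s0=s0, horizon=2.0)


class TestMeanArmRisk:
    def test_unchanged_markers_equal_risk(self):
        model = toy_model()
        t = uniform_shift_trial(100, 0.0, seed=1)
        for arm in ("treated", "placebo"):
            rb = ps.mean_arm_risk(model, t, arm, "baseline")
            rm = ps.mean_arm_risk(model, t, arm, "month6")
            assert rb == rm

    def test_reduced_harmful_marker_lowers_risk(self):
        model = toy_model(beta=0.5)
        t = uniform_shift_trial(200, -1.0, seed=2)
        assert ps.mean_arm_risk(model, t, "treated", "month6") < ps.mean_arm_risk(
            model, t, "treated", "baseline"
        )

    def test_three_patient_closed_form(self):
        """Mean of three hand-computable risks 1 - S0^exp(beta x)."""
        model = toy_model(beta=0.3, s0_T=0.95)
        t = pd.DataFrame({
            "arm": ["treated"] * 3,
            "x_base": [0.0, 1.0, -1.0],
            "x_m6": [0.0, 1.0, -1.0],
        })
        expected = np.mean([1 - 0.95 ** math.exp(0.3 * x) for x in (0.0, 1.0, -1.0)])
        assert ps.mean_arm_risk(model, t, "treated", "baseline") == pytest.approx(
            expected, rel=1e-12
        )

    def test_empty_arm_rejected(self):
        model = toy_model()
        t = uniform_shift_trial(10, 0.0, seed=3)
        with pytest.raises(ValueError, match="empty"):
            ps.mean_arm_risk(model, t[t["arm"] == "treated"], "placebo", "baseline")

    def test_incomplete_markers_rejected(self):
        model = toy_model()
        t = uniform_shift_trial(10, 0.0, seed=4)
        t.loc[0, "x_m6"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            ps.mean_arm_risk(model, t, "treated", "month6")


class TestComputePreRRR:
    @pytest.mark.parametrize("form", ["ratio_of_ratios", "adjusted_difference"])
    def test_identical_arms_zero_rrr(self, form):
        """When both arms share the same change distribution the
        predicted RRR is exactly zero."""
        model = toy_model()
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        chg = rng.normal(-0.2, 0.1, 50)
        t = pd.DataFrame({
            "arm": ["treated"] * 50 + ["placebo"] * 50,
            "x_base": np.r_[x, x],
            "x_m6": np.r_[x + chg, x + chg],
        })
        res = ps.compute_pre_rrr(model, t, ps.ScoreConfig(n_draws=10, seed=1, rrr_form=form))
        assert res.rrr == pytest.approx(0.0, abs=1e-12)
        assert res.form == form

    def test_rare_event_closed_form(self, rare_event_model):
        """Uniform treated shift delta, rare events: RRR ->
        100 * (1 - exp(beta_hat * delta))."""
        model, _ = rare_event_model
        delta = -0.8
        t = uniform_shift_trial(4000, delta, seed=6)
        res = ps.compute_pre_rrr(model, t, ps.ScoreConfig(n_draws=10, seed=2))
        b = model.fit.beta["x"]
        assert res.rrr == pytest.approx(100 * (1 - math.exp(b * delta)), rel=0.01)

    def test_forms_agree_for_small_risks(self, rare_event_model):
        model, _ = rare_event_model
        t = uniform_shift_trial(2000, -0.5, seed=7)
        r1 = ps.compute_pre_rrr(model, t, ps.ScoreConfig(n_draws=10, seed=3)).rrr
        r2 = ps.compute_pre_rrr(
            model, t, ps.ScoreConfig(n_draws=10, seed=3, rrr_form="adjusted_difference")
        ).rrr
        assert r1 == pytest.approx(r2, rel=0.02)

    def test_recovery_against_true_rrr_oracle(self, kidney_outcome, score_config):
        """Marker-mediated generator: predicted RRR within joint
        Monte-Carlo error of the simulated truth (matched populations
        so the risk scales coincide)."""
        specs = ps.trial_marker_specs()
        bg_cfg = ps.CohortConfig(n=5000, marker_specs=specs, seed=71)
        bg = ps.generate_background(bg_cfg, kidney_outcome)
        model = ps.fit_risk_model(bg, "kidney", list(MARKER_NAMES))
        tr_cfg = ps.default_trial_config(n=5000, seed=72)
        eff = ps.calibrated_effect_profile()
        trial = ps.generate_trial(tr_cfg, eff, kidney_outcome)
        pred = ps.compute_pre_rrr(model, trial, score_config)
        oracle = ps.true_rrr(kidney_outcome, eff, model.horizon, tr_cfg, n_sim=100_000, seed=73)
        assert pred.rrr == pytest.approx(oracle, abs=4.0)

    def test_zero_baseline_risk_rejected(self):
        model = toy_model()
        t = uniform_shift_trial(10, 0.0, seed=8)
        t["x_base"] = -1e9  # risk underflows to 0
        t["x_m6"] = -1e9
        with pytest.raises(ValueError, match="baseline risk"):
            ps.compute_pre_rrr(model, t, ps.ScoreConfig(n_draws=2, seed=1))

    def test_unit_rescaling_invariance(self, background, trial, score_config):
        """Refitting on an affinely rescaled marker leaves the RRR
        unchanged."""
        m1 = ps.fit_risk_model(background, "kidney", list(MARKER_NAMES))
        r1 = ps.compute_pre_rrr(model=m1, trial=trial, config=score_config).rrr
        bg2 = background.copy()
        tr2 = trial.copy()
        for t in (bg2, tr2):
            for col in ("sbp_base", "sbp_m6"):
                if col in t.columns:
                    t[col] = t[col] / 10.0 + 3.0  # mmHg -> cmHg + offset
        m2 = ps.fit_risk_model(bg2, "kidney", list(MARKER_NAMES))
        r2 = ps.compute_pre_rrr(model=m2, trial=tr2, config=score_config).rrr
        assert r1 == pytest.approx(r2, abs=1e-6)


class TestSingleMarker:
    def test_zero_change_marker_contributes_nothing(self, kidney_model, score_config):
        t = ps.generate_trial(
            ps.default_trial_config(n=1000, seed=81), ps.null_effect_profile()
        )
        t["hba1c_m6"] = t["hba1c_base"]
        res = ps.single_marker_rrr(kidney_model, t, "hba1c", score_config)
        assert res.rrr == pytest.approx(0.0, abs=1e-12)

    def test_single_equals_full_when_only_one_marker_moves(
        self, kidney_model, score_config
    ):
        eff = ps.null_effect_profile()
        eff.effects["sbp"] = ps.MarkerEffect(treated_extra=-8.0, change_sd=1e-6)
        t = ps.generate_trial(ps.default_trial_config(n=2000, seed=82), eff)
        for m in MARKER_NAMES:
            if m != "sbp":
                t[f"{m}_m6"] = t[f"{m}_base"]
        full = ps.compute_pre_rrr(kidney_model, t, score_config).rrr
        single = ps.single_marker_rrr(kidney_model, t, "sbp", score_config).rrr
        assert single == pytest.approx(full, rel=1e-9)

    def test_log_rr_decomposition_rare_events(self, rare_event_model):
        """With rare events and uniform changes, single-marker log
        relative risks add up to the full-model log relative risk."""
        model, outcome = rare_event_model
        # two-marker rare model
        specs = {
            "x": ps.MarkerSpec("x", "", "normal", 0.0, 1.0),
            "y": ps.MarkerSpec("y", "", "normal", 0.0, 1.0),
        }
        cfg = ps.CohortConfig(n=40_000, marker_specs=specs, correlation=np.eye(2), seed=83)
        out2 = ps.OutcomeConfig(
            name="r2", coefficients={"x": 0.3, "y": -0.4},
            baseline_hazard=0.001, censoring_years=3.0,
        )
        bg = ps.generate_background(cfg, out2)
        m2 = ps.fit_risk_model(bg, "r2", ["x", "y"])
        rng = np.random.default_rng(84)
        xv = rng.standard_normal(2000)
        yv = rng.standard_normal(2000)
        arm = np.array(["treated", "placebo"])[np.arange(2000) % 2]
        tr = pd.DataFrame({
            "arm": arm,
            "x_base": xv, "y_base": yv,
            "x_m6": xv + np.where(arm == "treated", -0.5, 0.0),
            "y_m6": yv + np.where(arm == "treated", 0.4, 0.0),
        })
        cfg_s = ps.ScoreConfig(n_draws=5, seed=85)
        full = ps.compute_pre_rrr(m2, tr, cfg_s).rrr
        parts = [
            ps.single_marker_rrr(m2, tr, m, cfg_s).rrr for m in ("x", "y")
        ]
        log_full = math.log(1 - full / 100)
        log_sum = sum(math.log(1 - p / 100) for p in parts)
        assert log_full == pytest.approx(log_sum, abs=0.01)

    def test_unknown_marker_rejected(self, kidney_model, trial, score_config):
        with pytest.raises(KeyError, match="nonesuch"):
            ps.single_marker_rrr(kidney_model, trial, "nonesuch", score_config)


class TestCIResample:
    def test_zero_se_collapses_to_point(self, trial):
        model = toy_model(se=1e-12)
        t = uniform_shift_trial(500, -0.5, seed=9)
        res = ps.compute_pre_rrr(model, t, ps.ScoreConfig(n_draws=50, seed=4))
        assert res.ci_low == pytest.approx(res.rrr, abs=1e-6)
        assert res.ci_high == pytest.approx(res.rrr, abs=1e-6)

    def test_doubling_ses_does_not_narrow_ci(self):
        t = uniform_shift_trial(500, -0.5, seed=10)
        widths = []
        for se in (0.05, 0.1):
            model = toy_model(se=se)
            lo, hi, _ = ps.ci_resample(model, t, ps.ScoreConfig(n_draws=100, seed=5))
            widths.append(hi - lo)
        assert widths[1] >= widths[0]

    def test_ci_covers_true_coefficient_rrr(self, kidney_outcome):
        """Coverage spot check of what the resampling CI models:
        uncertainty in the fitted coefficients.  Across replicate
        background cohorts (fixed trial), the CI contains the RRR
        evaluated at the true generating coefficients in most
        replicates.  (Trial-level sampling noise is deliberately outside
        the interval's scope.)"""
        from prescore.score import _point_rrr

        trial = ps.generate_trial(
            ps.default_trial_config(n=4000, seed=555), ps.calibrated_effect_profile()
        )
        beta_true = np.array([kidney_outcome.coefficients[m] for m in MARKER_NAMES])
        hits = 0
        reps = 8
        for s in range(reps):
            bg = ps.generate_background(
                ps.default_background_config(n=2500, seed=1000 + s), kidney_outcome
            )
            model = ps.fit_risk_model(bg, "kidney", list(MARKER_NAMES))
            res = ps.compute_pre_rrr(model, trial, ps.ScoreConfig(n_draws=80, seed=s))
            truth = _point_rrr(model, trial, "ratio_of_ratios", beta_override=beta_true)
            hits += res.ci_low <= truth <= res.ci_high
        assert hits >= reps - 2

    def test_n_draws_below_two_rejected(self):
        with pytest.raises(ValueError, match="n_draws"):
            ps.ScoreConfig(n_draws=1)


class TestObservedRRR:
    def test_null_generator_near_zero(self, kidney_outcome):
        t = ps.generate_trial(
            ps.default_trial_config(n=6000, seed=91),
            ps.null_effect_profile(),
            kidney_outcome,
        )
        rrr, lo, hi = ps.observed_rrr(t, "kidney")
        assert lo < 0 < hi

    def test_recovers_generating_hazard_ratio(self):
        """Pure direct effect log HR = ln 0.7 -> observed RRR ~ 30%."""
        outcome = ps.OutcomeConfig(
            name="d", coefficients={m: 0.0 for m in MARKER_NAMES},
            baseline_hazard=0.05, censoring_years=3.1,
            direct_log_hr=math.log(0.7),
        )
        t = ps.generate_trial(
            ps.default_trial_config(n=7020, seed=92), ps.null_effect_profile(), outcome
        )
        rrr, lo, hi = ps.observed_rrr(t, "d")
        assert lo < 30.0 < hi
        assert rrr == pytest.approx(30.0, abs=10.0)

    def test_matches_lifelines(self, trial):
        rrr, lo, hi = ps.observed_rrr(trial, "kidney")
        df = pd.DataFrame({
            "treated": (trial["arm"] == "treated").astype(float),
            "T": trial["time_kidney"],
            "E": trial["event_kidney"],
        })
        cph = CoxPHFitter().fit(df, "T", "E")
        assert rrr == pytest.approx(100 * (1 - math.exp(cph.params_.iloc[0])), abs=0.01)

    def test_arm_permutation_flips_log_rr(self, trial):
        rrr, *_ = ps.observed_rrr(trial, "kidney")
        flipped = trial.copy()
        flipped["arm"] = np.where(flipped["arm"] == "treated", "placebo", "treated")
        rrr_f, *_ = ps.observed_rrr(flipped, "kidney")
        assert math.log(1 - rrr / 100) == pytest.approx(
            -math.log(1 - rrr_f / 100), abs=1e-6
        )

    def test_zero_events_in_arm_rejected(self, trial):
        t = trial.copy()
        t.loc[t["arm"] == "placebo", "event_kidney"] = 0
        with pytest.raises(ValueError, match="zero events"):
            ps.observed_rrr(t, "kidney")
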