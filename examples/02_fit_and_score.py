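"""Fit the marker -> outcome Cox model and compute the PRE score.

The treatment effect in the generated trial is wholly marker-mediated,
so the predicted RRR should agree with the observed treatment-arm Cox
RRR — the framework's central correctness property.
"""

import prescore as ps
from prescore.markers import MARKER_NAMES

seed = 1

bg_cfg = ps.default_background_config(seed=seed)
kidney = ps.calibrate_baseline_hazard(bg_cfg, ps.default_kidney_outcome(), 0.178)
background = ps.generate_background(bg_cfg, kidney)

model = ps.fit_risk_model(background, "kidney", list(MARKER_NAMES))
print("fitted Cox coefficients (kidney endpoint):")
for m in model.markers:
    print(f"  {m:11s} beta = {model.fit.beta[m]:+.4f}  (SE {model.fit.se[m]:.4f})")
print(f"risk horizon: {model.horizon:.2f} years (median background follow-up)")

trial = ps.generate_trial(
    ps.default_trial_config(seed=seed + 1), ps.calibrated_effect_profile(), kidney
)
result = ps.compute_pre_rrr(model, trial, ps.ScoreConfig(n_draws=100, seed=seed))
obs, lo, hi = ps.observed_rrr(trial, "kidney")

print(f"\nPRE-predicted RRR: {result.rrr:.1f}% "
      f"(95% CI {result.ci_low:.1f} to {result.ci_high:.1f}, 100 coefficient draws)")
print(f"observed RRR:      {obs:.1f}% (95% CI {lo:.1f} to {hi:.1f})")
print("\nThe predicted interval reflects coefficient uncertainty only; the")
print("observed interval is the Wald interval of the treatment-arm hazard")
print("ratio.  With a fully marker-mediated effect the two point estimates")
print("agree within Monte-Carlo error.")
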