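"""Single-marker attributions and subgroup scoring.

Each single-marker score advances only that marker to its observed
month-6 value (all others held at baseline) and reuses the full
multivariable coefficient vector.  Subgroups are baseline-only filters;
because the score is a ratio, the overall score is *not* the weighted
average of subgroup scores.
"""

import prescore as ps
from prescore.markers import MARKER_NAMES

seed = 1

bg_cfg = ps.default_background_config(seed=seed)
kidney = ps.calibrate_baseline_hazard(bg_cfg, ps.default_kidney_outcome(), 0.178)
model = ps.fit_risk_model(
    ps.generate_background(bg_cfg, kidney), "kidney", list(MARKER_NAMES)
)
trial = ps.generate_trial(
    ps.default_trial_config(seed=seed + 1), ps.calibrated_effect_profile(), kidney
)
cfg = ps.ScoreConfig(n_draws=100, seed=seed)

print("single-marker predicted RRR (kidney endpoint):")
for m in MARKER_NAMES:
    r = ps.single_marker_rrr(model, trial, m, cfg)
    print(f"  {m:11s} {r.rrr:+6.1f}%  ({r.ci_low:+.1f} to {r.ci_high:+.1f})")

full = ps.compute_pre_rrr(model, trial, cfg)
print(f"  {'all markers':11s} {full.rrr:+6.1f}%  "
      f"({full.ci_low:+.1f} to {full.ci_high:+.1f})")

print("\nsubgroup scores:")
for sg in (ps.uacr_at_least(30), ps.uacr_below(30), ps.empa_kidney_like()):
    sub = ps.apply_subgroup(trial, sg)
    r = ps.compute_pre_rrr(model, sub, cfg)
    print(f"  {sg.name:17s} n={len(sub):5d}  RRR {r.rrr:5.1f}% "
          f"({r.ci_low:.1f} to {r.ci_high:.1f})")

# Albuminuria dominates the kidney prediction, so the elevated-UACR
# subgroup shows a larger predicted benefit than the normal-UACR one.
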