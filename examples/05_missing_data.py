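"""Missing marker values: MCAR/MAR injection, PMM imputation, pooling.

Month-6 values are blanked, imputed m times by chained-equation
predictive mean matching, each completed dataset is scored, and the
point estimates and CI bounds are pooled by averaging.
"""

import numpy as np

import prescore as ps
from prescore.markers import MARKER_NAMES

seed = 1

bg_cfg = ps.default_background_config(seed=seed)
kidney = ps.calibrate_baseline_hazard(bg_cfg, ps.default_kidney_outcome(), 0.178)
model = ps.fit_risk_model(
    ps.generate_background(bg_cfg, kidney), "kidney", list(MARKER_NAMES)
)
trial = ps.generate_trial(
    ps.default_trial_config(n=3000, seed=seed + 1), ps.calibrated_effect_profile(), kidney
)
cfg = ps.ScoreConfig(n_draws=50, seed=seed)
complete_rrr = ps.compute_pre_rrr(model, trial, cfg).rrr

holey = ps.inject_missingness(
    trial,
    ps.MissingnessConfig(
        mechanism="MAR",
        proportions={"hba1c_m6": 0.15, "uacr_m6": 0.10},
        mar_covariate="age",
        mar_strength=1.0,
    ),
    seed=seed,
)
print(f"blanked: {holey['hba1c_m6'].isna().sum()} HbA1c and "
      f"{holey['uacr_m6'].isna().sum()} UACR month-6 values "
      f"(missingness increases with age)")

completed = ps.impute_pmm(holey, ps.ImputationConfig(m=5, k=5, n_iter=10, seed=seed))
rrrs = [ps.compute_pre_rrr(model, t, cfg).rrr for t in completed]
pooled, total_var = ps.pool_estimates(rrrs, [0.0] * len(rrrs))

print(f"per-imputation RRR: {[round(r, 2) for r in rrrs]}")
print(f"pooled RRR: {pooled:.1f}%  (between-imputation SD "
      f"{np.std(rrrs, ddof=1):.2f} pp)")
print(f"complete-data RRR:  {complete_rrr:.1f}%")
print("\nPMM only ever fills in values observed elsewhere in the column,")
print("so the imputed month-6 distributions stay realistic; under MAR the")
print("pooled score stays close to the complete-data score.")
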