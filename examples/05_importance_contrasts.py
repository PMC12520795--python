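"""Permutation importance and beta-GLMM region contrasts.

Simulates a scaled-importance table in which predictor p2 is genuinely more
influential in the native range (a +1 logit shift), fits the beta regression
mixed model, and reports estimated marginal-mean contrasts: negative values
mean "more influential in the invasive range".
"""

import numpy as np

from invasdm import fit_beta_glmm, region_contrasts
from invasdm.studies import simulate_importance_table

rng = np.random.default_rng(17)
table = simulate_importance_table(rng, n_runs=50, shift_predictor="p2", shift=1.0)
print(f"importance table: {len(table)} rows "
      f"({table['run'].nunique()} runs x 2 regions x 3 predictors)")

fit = fit_beta_glmm(table)
print(f"converged: {fit.converged}; run-intercept sd = {fit.sigma:.3f} "
      f"(simulated 0.3); log-likelihood {fit.loglik:.1f}")

contrasts = region_contrasts(fit, invasive_region="invasive")
print(contrasts.round(4).to_string(index=False))
print("p2's contrast should sit near +1 (more influential in the native range);"
      " p1/p3 near 0.")
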