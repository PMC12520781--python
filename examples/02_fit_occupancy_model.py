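"""Fit candidate dynamic occupancy models for one species and select by AIC.

Simulates a species whose colonization/extinction genuinely follow forest
cover, fits the four candidate dynamics covariates (constant, year,
temperature, forest), and checks goodness-of-fit by parametric bootstrap.
"""

import numpy as np

from occutrends import (
    SimConfig,
    fit_species,
    generate_covariates,
    gof_parametric_bootstrap,
    occupancy_trajectory,
    simulate_detection_history,
    standardize_covariates,
)
from occutrends.synth import SpeciesParams

truth = SpeciesParams(name="sp", gamma_intercept=-1.0, gamma_slope=2.0,
                      eps_intercept=-1.0, eps_slope=-2.0,
                      p_intercept=0.0, p_effort=1.0, dynamics="forest")
cfg = SimConfig(n_species=1, n_regions=30, n_years=60, species_params=[truth],
                seed=7, forest_midpoint=30, forest_rate=0.2)
data, sim_truth = simulate_detection_history(cfg)
cov = generate_covariates(cfg)
std = standardize_covariates(cov, data.effort)

best, aic_table = fit_species(data, cov, std, "sp", seed=1)
print(aic_table.to_string(index=False))
print(f"\nselected dynamics covariate: {best.spec.dynamics} (truth: forest)")
for name, est, se in zip(best.coef_names, best.coef, best.se):
    print(f"  {name:>16s}: {est:+.3f} +/- {se:.3f}  (logit scale)")

gof = gof_parametric_bootstrap(best, n_sim=99, seed=2)
print(f"\nGOF bootstrap p = {gof.p_value:.2f} "
      f"({'poor fit' if gof.poor_fit else 'adequate fit'})")

traj = occupancy_trajectory(best, mode="smoothed", burn_in_years=4)
mean_occ = traj.prob[:, ~traj.burn_in].mean(axis=0)
print(f"mean occupancy across regions: {mean_occ[0]:.2f} (start) -> "
      f"{mean_occ[-1]:.2f} (end); truth declines as forest is lost")
# The AIC table shows how clearly the forest candidate beats year/temperature
# when the covariate's shape is distinct from a linear trend.
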