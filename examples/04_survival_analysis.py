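"""The survival stage: Cox regression, optimal cutpoint, KM and log-rank.

Simulates a 200-patient cohort whose hazard halves per unit of a biomarker
(true log hazard ratio = -log 2), then recovers the effect, dichotomizes
the biomarker at the maximally selected log-rank cutpoint, and tests the
groups.
"""

import numpy as np

from histokurt import (
    SurvivalSimSpec, fit_cox, km_curve, logrank_test, maxstat_cutpoint,
    simulate_survival,
)

spec = SurvivalSimSpec(
    n_patients=200, beta=-np.log(2), baseline_hazard=1.0, censor_rate=0.3,
    covariate_model="continuous-standardized", seed=0,
)
table = simulate_survival(None, spec)

fit = fit_cox(table, ["covariate"])
row = fit.summary.loc["covariate"]
print(f"continuous Cox: HR per unit = {row['hazard_ratio']:.3f} "
      f"(95% CI {row['ci_lo']:.3f}-{row['ci_hi']:.3f}, p = {row['p']:.2e}); "
      f"true HR = {np.exp(-np.log(2)):.3f}")

cut = maxstat_cutpoint(table, "covariate", minprop=0.1)
print(f"maxstat cutpoint = {cut.cutpoint:.3f} "
      f"(max standardized log-rank statistic {cut.max_statistic:.2f}, "
      f"adjusted p = {cut.adjusted_p:.2e})")

table["group"] = np.where(table["covariate"] > cut.cutpoint, "high", "low")
chi2, p = logrank_test(table, "group")
km = km_curve(table, "group")
for g, curve in km.items():
    print(f"  {g}: n = {int(curve.at_risk[0])}, "
          f"median survival ~ {curve.times[np.searchsorted(-curve.survival, -0.5)]:.2f}")
print(f"log-rank chi2 = {chi2:.2f}, p = {p:.2e}")
print("\nHR < 1: higher biomarker is protective; the cutpoint splits the "
      "cohort where\nthe standardized log-rank statistic peaks, with a "
      "multiplicity-adjusted p-value.")
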