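"""Simulate the default medaka cohort and contrast the sexes' survival.

Builds the calibrated synthetic cohort (1500 fish per sex, entering
observation at 3 months, censored at 30), estimates left-truncated
Kaplan-Meier curves per sex and runs the logrank test.
"""

import telovita as tv

cfg = tv.SimConfig(seed=1)
cohort = tv.cohort_frame(tv.simulate_cohort(cfg))

for sex, label in (("M", "males"), ("F", "females")):
    sub = cohort[cohort["sex"] == sex]
    med = tv.km_median(tv.km_estimate(sub))
    print(f"{label}: n = {len(sub)}, median lifespan = {med.median:.2f} months "
          f"(95% CI {med.ci_lower:.2f}-{med.ci_upper:.2f})")

lr = tv.logrank_test(cohort[cohort["sex"] == "M"], cohort[cohort["sex"] == "F"])
print(f"logrank: chi2 = {lr.chi_square:.2f}, df = {lr.df}, N = {lr.n}, "
      f"p = {lr.p_value:.4f}")
print("A p-value below 0.05 means the female survival advantage (the "
      "longevity gender gap) is detectable at this cohort size.")
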