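# telovita

Sex-specific telomere attrition, survival and cross-species age scaling in
the Japanese medaka (*Oryzias latipes*).

Female medaka live longer than males and carry longer telomeres, and their
plasma estradiol falls off a peak at 8 months much as it does across human
menopause — which makes this small fish an attractive vertebrate model for
asking how sex hormones, telomerase and telomere length connect to the
longevity gender gap. `telovita` implements the full quantitative chain of
that analysis as a tested, reusable Python library:

* **Survival** — Kaplan–Meier estimation adjusted for left truncation
  (fish enter observation at sexual maturation, ~3 months, so earlier
  deaths are unobservable) and right censoring, with Greenwood
  complementary-log-log confidence bands, median lifespans with CIs, and a
  truncation-aware two-group logrank test.
* **Telomere attrition** — nonlinear least-squares fits of the asymptotic
  decay model *TRF(t) = Plateau + (TRF₀ − Plateau)·e^(−λt)* of mean
  terminal-restriction-fragment (TRF) length against age, per organ and
  sex, with rate-constant CIs and overlap comparisons.
* **TRF densitometry** — mean TRF length from 1-D Southern-blot lane
  profiles calibrated against a λ HindIII/EcoRI ladder, using the
  intensity-corrected estimator ΣOD / Σ(OD/L).
* **Assays** — Cq extraction from semi-log qPCR amplification plots,
  relative telomerase activity by the 2^(−ΔCq) method, and plasma-protein
  normalisation of hormone concentrations.
* **Critical telomere length** — the survival-prediction model: pair
  age-group survival probabilities with age-group mean liver TRF, fit
  S = a + b·TRF, and extrapolate to S = 0. The x-intercept
  L_crit = −a/b (≈3.8 kb in medaka liver) is the telomere length at which
  organismal survival is predicted to vanish; uncertainty comes from a
  bootstrap that resamples fish and panel replicates jointly.
* **Age conversion** — the through-origin quadratic
  *Age_medaka = a·Age_human + b·Age_human²* fitted to life-history
  hallmarks (maturation, median and maximum lifespan), with its exact
  inverse.
* **Statistics** — Spearman correlations, Benjamini–Hochberg FDR, Student's
  t, two-way ANOVA with interaction, and Tukey HSD with compact letter
  display, as thin contract-checked wrappers over scipy/statsmodels.

Because no individual-level medaka husbandry records are publicly
available, the package
ships a seeded synthetic cohort generator (`cohortsim`) calibrated to the
study conditions: median lifespans of 13.7 (♂) and 14.6 (♀) months,
initial TRF in the 12–17 kb range decaying toward a plateau, a hepatic
death threshold of 3.8 ± 0.3 kb, hormone trajectories peaking at 8 months,
and the sex/organ-specific rank-correlation structure between hormones,
telomerase activity and TRF (via a Gaussian copula with the
2·sin(πρ/6) rank-to-linear conversion). Every downstream module is
exercised end-to-end against this generator.

## Worked example

```python
import telovita as tv

cfg = tv.SimConfig(seed=1)               # the calibrated default cohort
cohort = tv.cohort_frame(tv.simulate_cohort(cfg))
for sex in ("M", "F"):
    med = tv.km_median(tv.km_estimate(cohort[cohort.sex == sex]))
    print(sex, round(med.median, 2))
```

prints (seed 1):

```
M 13.5
F 14.68
```

— the left-truncated KM medians of the two sexes, to be read against the
calibration targets of 13.7 and 14.6 months. Continuing with the same run
(`examples/critical_length.py`):

```
pooled: L_crit = 3.71 kb (95% bootstrap CI 2.63-4.13 kb), R2 = 0.875
M     : L_crit = 3.69 kb (95% bootstrap CI 2.57-4.46 kb), R2 = 0.842
F     : L_crit = 3.84 kb (95% bootstrap CI 2.33-4.57 kb), R2 = 0.923
```

The pooled extrapolation recovers the generator's 3.8 kb hepatic death
threshold inside its bootstrap CI, and the overlapping per-sex intervals
show the critical length is not sex-dependent. The age-conversion model
(`examples/age_conversion.py`) inverts to

```
medaka 8 months  ->  human 46.0 years
medaka 12 months ->  human 60.4 years
```

mapping the female estrogen-decline window onto the human menopausal age
range. Each script in `examples/` demonstrates one capability and prints a
line on what the numbers mean; a thin CLI (`telovita simulate|survival|
decay|trf|assay|correlate|critical|ageconvert|pipeline`) wraps the same
functions for shell use, and `telovita pipeline --seed 1 --out-dir out/`
writes every stage's tables plus `report.json` and a digest manifest.

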