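# Methods

This note records the models implemented in `telovita`, the generator that
stands in for the undeposited fish records, the calibration of its
defaults, and the numerical choices a maintainer would want to know.

## Survival estimation

Fish enter observation at the truncation age (default 3 months, sexual
maturation); deaths before entry are structurally unobservable. The
Kaplan–Meier estimator therefore uses delayed-entry risk sets
`{entry < t ≤ exit}`; at tied times deaths are processed before
censorings. Confidence bands are Greenwood variances transformed to the
complementary log-log scale, which keeps them inside [0, 1] (plain
Greenwood bands do not). The median is the first time S(t) ≤ 0.5, with a
plateau resolved to its left endpoint; its CI is read off the first 0.5
crossings of the two bands. The logrank statistic uses the same
delayed-entry risk sets, hypergeometric variance with the (n−d)/(n−1)
correction, and χ² reference with df = 1. `lifelines` (which supports
`entry=` for the estimator but not for the logrank test) serves as an
independent oracle in the tests, next to a first-principles product-limit
enumeration.

## Telomere attrition model

Mean TRF versus age is fitted per organ × sex as

    TRF(t) = Plateau + (TRF0 − Plateau) · exp(−λ t)

by nonlinear least squares with a self-starting rule (plateau ← min TRF;
TRF0 ← TRF at the earliest age; λ ← log-linear slope of the shifted
response), five jittered restarts, and box constraints λ ∈ (0, 10],
Plateau, TRF0 ≥ 0 for conditioning. λ is reported per month, with a
linearised Wald CI (`ci_lam_scaled` rescales to other time units; note
that rate CIs quoted per year are 12× the per-month values, and the
package does not attempt to force any particular printed magnitude).
Two R² values are carried: against replicate observations (depressed by
within-age pooling noise) and against the per-age means, which is the
figure-level convention. Rates are compared by CI overlap (a
deliberately conservative criterion) alongside a Wald CI
on the difference. Inverse-SEM² weighting is available but off by
default. No longitudinal or mixed-effects structure is modelled: every
panel is a destructive cross-section.

## TRF densitometry

A lane profile is optical density versus migration distance. The ladder
calibration interpolates log10(size) piecewise-linearly against band
position (so the midpoint of two bands maps to their geometric mean size)
and continues the terminal segments when extrapolating, with a flag. The
default mean-TRF estimator is the intensity-corrected form
ΣOD / Σ(OD/L): hybridisation signal scales with telomeric repeat content,
i.e. with fragment length, so OD/L counts molecules. The plain weighted
mean Σ(OD·L)/ΣOD is available behind a flag; on a lognormal smear it
exceeds the corrected estimator by the smear's length dispersion, and both
are reported by the blot example. The default analysis window is
1.5–21.2 kb (the λ HindIII/EcoRI ladder span). Background subtraction is
rolling-minimum (window in bins) or a straight line through the profile
endpoints, clipped at zero.

## Assays

Cq is the fractional cycle at which fluorescence crosses a threshold,
interpolated linearly in log-fluorescence (the semi-log plot convention);
a curve that never crosses, or is already above threshold at cycle 1,
yields an undetermined Cq that propagates as censored, never as zero.
Relative telomerase activity is 2^(−ΔCq) against a user-designated
reference sample; triplicates are summarised by mean Cq before ΔCq is
formed (a mean-of-activities variant exists behind a flag). Hormone
concentrations are divided by plasma protein; the output carries an
explicit unit string ("… per mg protein") rather than assuming units.

## Critical telomere length

For each sampling age the KM survival probability is paired with the mean
liver TRF of fish sampled at that age — cross-sectional pooling, because
TRF measurement is destructive and longitudinal pairs cannot exist. An
OLS line S = a + b·TRF is fitted (per sex and pooled over both sexes' age
points) and extrapolated to S = 0, giving L_crit = −a/b. The
extrapolation always leaves the observed TRF range and is flagged as
such; predictions are clamped to [0, 1]. Uncertainty comes from a
nonparametric bootstrap (default B = 1000, percentile CI) that resamples
fish within sex and panel replicates within age × sex and refits the
entire KM → pairing → OLS chain, so the CI reflects every noise source at
once. A fit with non-positive slope is an error: extrapolating it would
be meaningless. The gill is deliberately not analysed this way — its TRF
levels off at old age, so the line never reaches zero.

## Age conversion

A through-origin quadratic `Age_medaka = a·x + b·x²` (x in human years)
is least-squares fitted to five hallmark pairs: sexual maturation
(human 12–15 y, midpoint 13.5 by default, exposed as a parameter), median
lifespan per sex (65.7 → 13.7, 70.1 → 14.6) and maximum recorded lifespan
per sex (116.1 → 32.0, 122.4 → 39.5). R² is computed about zero (the
no-intercept convention, 0.996 on these pairs) and about the mean
(0.987), both reported. The inverse is the positive quadratic root. The
reference model's quadratic coefficient is sometimes quoted as 0.0171;
that decimal placement reproduces neither the hallmark data (the fit
gives 0.00177) nor the documented 8 → 46.0 / 12 → 60.4 interpolations,
both of which 0.00171 reproduces exactly, so 0.00171 is the default and
the as-printed variant is kept, flagged, for comparison.

## The synthetic cohort generator

Each simulated fish draws an initial liver TRF (per-sex normal), a gill
TRF0 tracking it with small jitter, a hepatic death threshold
θ ~ N(3800, 300) bp shared between the sexes, and a private lognormal
aging-rate multiplier applied to both organs. Organ TRF follows the
asymptotic decay above; the fish dies when liver TRF crosses θ, or
earlier under a sex-specific exponential background hazard, whichever
comes first. Deaths before the truncation age are discarded (left
truncation); exits beyond the censoring age (30 months) are censored.
Panels sample live fish destructively: 15 replicates per sex per age,
each a pool of 3 fish (arithmetic pooling by default; lognormal-mean
pooling available, since the original pooling arithmetic is unstated),
with 4 % lognormal measurement noise.

Assay panels draw a latent Gaussian vector whose correlation is the
2·sin(πρ_S/6) conversion of the configured Spearman targets — the
hormone-versus-TA/TRF entries of the observed correlation table, a single
inter-hormone Spearman of 0.5 (unreported; one moderate value chosen for
physiological plausibility, verified to keep all four sex × organ
matrices positive definite), zeros elsewhere — and maps it through
monotone marginals: lognormal hormones and telomerase activity centred on
gamma-density-shaped age trajectories peaking at 8 months (sharp female
E2 decline, flatter male profiles; androgens mirrored), and a normal TRF
marginal on the organ's mean decay curve. Monotone marginals preserve
ranks, so the empirical Spearman converges to the target. A non-PSD
target matrix is an error (with a nearest-PSD hint), never silently
repaired. Blot lanes are discretised lognormal smears whose
molecule-weighted mean equals the requested TRF (computed in log space so
arbitrarily narrow smears stay representable); qPCR curves are logistic
sigmoids doubling per cycle in the exponential phase. All randomness
derives from one seed through named CRC-keyed substreams, so outputs are
bytewise reproducible and independent of call order.

### Calibration of the defaults

The generator's free constants were calibrated once, against the study
conditions themselves, by `scripts/calibrate_generator.py`, and frozen:

* The two liver rate constants (M 0.0806, F 0.1416 /month) are bisected
  so that the **average n = 1500 KM median** over 48 replicate cohorts
  lands on 13.7 / 14.6 months — calibrating the estimator actually
  reported, not just the distributional median. Gill rates are half the
  liver rates.
* The background hazard is sex-specific (M 0.034, F 0.002 /month). A pure
  telomere-mechanism location shift that respects the 0.9-month median
  gap separates the sexes too weakly for the logrank test to detect
  reliably; concentrating part of the female advantage in mid-life
  background mortality matches the observed survival-curve geometry (the
  female advantage is largest at 4–15 months) and gives the test ~80 %
  power at this cohort size.
* The rate-heterogeneity σ = 0.755 and TRF0 parameters
  (M 12500 ± 2500, F 16500 ± 2500 bp) jointly set the shape of the
  survival-versus-mean-TRF cloud. With little heterogeneity that relation
  is strongly convex and the zero-survival extrapolation lands far below
  the death threshold; individual rate heterogeneity plus survivor bias
  (slow-aging fish dominate the old panels) straighten it to R² ≈ 0.85–0.9
  and centre the pooled extrapolated L_crit on the 3.8 kb threshold.

What the generator does **not** emulate: tank- or cohort-level clustering
of mortality, seasonal effects, measurement drift between blots,
longitudinal within-fish correlation (all sampling is cross-sectional),
and any feedback of hormones on telomere dynamics — the hormone/TA/TRF
dependence is purely a static copula. A passing test suite therefore
shows the chain recovers the truths of *this* mechanism at the study's
sample sizes, not that the mechanism is the biology.

### Finite-sample behaviour worth knowing

* At n = 1500/sex the KM medians carry a seed-to-seed SD of ≈0.35 months,
  and the pooled L_crit of ≈0.4 kb; single-run values routinely differ
  from the calibration targets by those amounts. The bootstrap CI
  (typically ±0.5–0.8 kb) is the honest uncertainty statement for one
  run.
* Fitted decay parameters on cohort-derived panels are *population*
  summaries under heterogeneity and survivor bias: the apparent plateau
  sits well above the individual-level plateau, and the fitted λ below
  the median individual rate. This is a feature of cross-sectional
  aggregation, not a fitting defect; the fitter recovers exact parameters
  to 1e-6 on noise-free individual-level curves, and its Wald λ-CI covers
  the truth at the nominal 95 % on homogeneous panels.
* Pooled-over-age correlation tables mix the within-age copula with
  shared age trajectories, so they need not match the configured
  within-age targets; single-age panels do.

## Numerical choices and degenerate inputs

Infeasible individual draws (θ ≥ TRF0 or θ ≤ plateau) are resampled with
a bounded retry budget, then rejected as a configuration error. An empty
observable cohort (censoring before truncation) warns and returns an
empty collection. Constant vectors make Spearman undefined (error);
groups with zero variance and equal means make t undefined (error);
empty ANOVA cells are rejected with a pointer to cell-means
parameterisation. BH adjustment enforces monotonicity from the largest
rank and clips at 1; it is deliberately tested for monotonicity and
domination, not idempotence, which does not hold for the step-up
procedure in general. Tukey letters come from a greedy clique cover of
the non-significant-pair graph in descending-mean order; letters are a
presentation layer only. The pipeline driver runs stages under a
partial-completion policy: a stage failure is recorded in the report and
manifest and later stages that do not depend on it still run; reruns of
the same config and seed reproduce output digests bytewise.

## Problem sizes used by tests and the acceptance run

Tests run the full chain at the study design (1500 fish/sex, 15 pooled
replicates per sex per age, B = 1000 bootstrap for the acceptance-level
check; B = 150–300 in auxiliary tests), Monte-Carlo checks at 500
replicates (λ-CI coverage) and 1000 replicates (logrank type-I error at
n = 60 per group), and brute-force oracle comparisons on random cohorts
of ≤ 20 records. The whole suite completes in well under five minutes;
the acceptance script in under a minute.
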