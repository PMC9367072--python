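# Methods

## The estimand and the estimator

`stratmr` estimates the causal effect of an inflammatory exposure —
high-sensitivity C-reactive protein (hsCRP, mg/dL), a downstream
biomarker of IL-6 receptor signaling — on time-to-event cardiovascular
outcomes, using a weighted genetic risk score (GRS) as an instrumental
variable. The GRS collapses a set of variants at one locus into

    score_i = Σ_j w_j · d_ij

with per-allele weights w_j in exposure units, so the first-stage slope
β_GX (ordinary least squares of exposure on score, covariate-adjusted) is
approximately 1 and the score inherits the exposure's scale. The
instrument–outcome association β_GY is the log-hazard per unit score from
a covariate-adjusted Cox proportional-hazards model (Efron ties). The
causal estimate is the ratio of coefficients (Wald ratio)

    β_IV = β_GY / β_GX,

a log-hazard ratio per 1 mg/dL of exposure.

**Standard errors.** The default is the second-order delta expansion
se² = se_GY²/β_GX² + β_GY²·se_GX²/β_GX⁴; the first-order expansion
(se_GY/|β_GX|) and a Fieller interval are alternatives. The two stage
estimates come from the same sample; their covariance is set to zero,
which is the usual practice for this design and is logged as an
assumption. A warning is emitted when |β_GX|/se_GX < 2.

## Residual stratification

To study effect heterogeneity across exposure levels without breaking the
instrument, the cohort is stratified on the *residual* exposure

    r_i = x_i − β_GX · s_i,

i.e., measured exposure minus its genetically predicted component.
Stratifying on x itself conditions on a common descendant of the
instrument and the confounders (a collider) and induces a spurious
instrument–confounder association within strata; the residual is
orthogonal to the instrument by construction. Residuals are used only
for stratum *assignment*; stratum positions are medians of the measured
exposure, which is what the dose–response axis means.

Within each stratum the ratio estimator is re-applied, giving a localized
average causal effect (LACE) interpreted as the local slope of the causal
log-hazard curve h(x). By default the full-cohort β_GX is reused in every
stratum (the residual-method convention; it also stabilizes small
strata); per-stratum re-fitting is an option. Strata with zero events are
dropped, never merged — merging would silently change the quantile
semantics.

Heterogeneity across the K strata is tested with Cochran's Q
(inverse-variance weighted, chi-squared with K−1 df) and a linear trend
with an inverse-variance weighted meta-regression of LACE on stratum
median (fixed-effect covariance from the known stratum SEs; Wald normal
p-value — the strata are few, but each estimate is itself asymptotic).

## Fractional-polynomial dose–response synthesis

Each LACE is a local derivative of h(x), so the curve is recovered by
meta-regressing the LACEs on the *derivatives* of fractional-polynomial
(FP) bases evaluated at the stratum medians, powers from the conventional
family P = {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 denotes ln), then
integrating:

    h(x) = Σ_j θ_j (f_pj(x) − f_pj(x_ref)),   HR(x) = exp(h(x)),

anchored exactly at HR(x_ref) = 1. There is deliberately **no intercept**
in the derivative regression: a constant slope *is* the power-1 basis, so
an intercept would double-count linearity. Degree-2 models use the
standard repeated-power extension (x^p, x^p ln x). Pointwise confidence
bands come from the delta method on the coefficient covariance
(X'WX)^{-1}; no simultaneous bands.

**Non-linearity test.** statistic = 2·(loglik(best degree-1 FP) −
loglik(linear)), referred to chi-squared(1). Because the best power is
selected on the same data, this reference is mildly anticonservative; a
seeded permutation calibration (shuffling the LACE-to-median pairing) is
available as an option. The default reference exposure x_ref is the
minimum observed exposure, configurable.

**The ln scale.** The same analysis can be run per unit of ln-exposure.
Stratum estimates are chain-rule transformed (position ln m_k, LACE and
SE multiplied by m_k), which makes a linear FP on the ln scale exactly
equivalent — coefficient and all — to the power-0 FP on the absolute
scale. Because FP transforms need a positive argument, ln-scale positions
are shifted to a positive origin when necessary (the standard FP origin
convention); the shift cancels in the linear basis and is recorded in the
result for curve reconstruction.

## The synthetic cohort generator

The generator produces cohorts with the structure the estimators assume
and a *known* causal dose–response, so every stage has a
parameter-recovery oracle. Defaults emulate a large middle-aged
population biobank:

| parameter | default | meaning |
|---|---|---|
| n_variants | 26 | instrument variants, Hardy–Weinberg, no LD |
| allele_freqs | 0.08–0.48 | evenly spread effect-allele frequencies |
| variant_weights | ±0.066 mg/dL | alternating-sign per-allele effects |
| exposure_median | 1.35 mg/dL | marginal hsCRP median |
| exposure_log_sd | 1.0 | log-normal spread (IQR ≈ 0.67–2.80 with U) |
| confounder_effect | 0.35 | effect of latent U ~ N(0,1) on log-exposure |
| confounder_hazard | 0.30 | direct effect of U on the log-hazard |
| baseline_hazard | 0.0108 /yr | calibrated to ~11.6% incidence |
| followup_years | 9.0 | administrative censoring horizon |
| censor_rate | 0.012 /yr | independent loss to follow-up |
| theta | 0.10 | causal log-HR per 1 mg/dL (linear default) |

The exposure is a right-skewed log-normal base plus an **additive**
genetic contribution on the natural scale, x = exp(μ + σZ + cU) + Σ w_j
d_j, floored at 0.08 mg/dL — the minimum observed in the emulated cohort.
The additive form keeps the first stage linear, matching the ratio
estimator's assumption; the floor keeps log-scale analyses defined and
bounds the local slope 1/x of log-shaped causal functions (a lower floor
makes the lowest stratum's mean derivative explode and genuinely changes
the best-fitting FP transform, which would misrepresent the intended
log-shaped truth). Signed weights (effect alleles may raise or lower the
biomarker) keep the mean genetic shift small so the marginal median and
IQR are preserved.

Instrument strength is a free parameter; the default weight magnitude is
tuned so the score explains ~0.3% of exposure variance (first-stage
F ≈ 300 at n = 100,000), in the range typical of single-locus scores in
large biobanks.

Event times are exponential with log-hazard log(λ₀) + h(x) + 0.07·(age −
58) − 0.35·sex + 0.3·U, censored administratively and by an independent
exponential mechanism; h is configurable (linear, log, threshold, null).
The five clinical covariates (BMI, LDL-C, SBP, eGFR, HbA1c) load on U
with the sign of their observed hsCRP correlations.

**What the generator does not emulate:** linkage disequilibrium,
genotyping error, population structure (no principal components),
assessment-center or chip effects, age/sex effects *on the exposure*,
competing risks, and non-proportional hazards. Passing tests therefore
show that the estimators are correct under the model's assumptions, not
that those assumptions hold in any particular real cohort.

## Validation studies and sizes

The package validates itself with simulation studies
(`stratmr.validate`), run by the test suite and `scripts/acceptance.py`:

- **2SLS identity** — with a single instrument and a continuous outcome,
  the Wald ratio of the two fitted slopes equals the two-stage least
  squares slope computed by explicit projection (agreement ~1e-12).
- **Linear recovery** — replicate cohorts (n = 20,000) with θ = 0.10:
  mean estimate near 0.10, second-order-delta 95% CI coverage in the
  nominal range (measured ~97%: ignoring the positive one-sample
  covariance between β_GY and β_GX, corr ≈ 0.27 at this size, makes the
  interval mildly conservative), trend meta-regression flat, FP
  rejections near the nominal 5%.
- **Null calibration of the FP test** — run at the smallest cohort size
  (n = 8,000) at which the stratum LACE standard errors are themselves
  calibrated (z-score sd ≈ 1). At smaller sizes the small-stratum SEs
  overstate the noise (z-sd ≈ 0.87 at n = 3,000), deflating the
  likelihood-ratio statistic, and the check would measure se bias rather
  than test calibration. Measured rejection ≈ 4% at n = 8,000, ~7.5% at
  n = 20,000 — the power-selection anticonservatism and the delta-method
  conservatism roughly offset near the nominal level.
- **Log power** — cohorts (n = 50,000) with h(x) = 0.15 ln x: FP
  rejection rate and the frequency with which the log transform (power 0)
  is identified. At this size and instrument strength each decile LACE
  carries an SE of ~0.2, against which the curvature signal yields a
  likelihood-ratio non-centrality of only ~4–5 (the Cox fit also
  attenuates the steep low-exposure strata), so the observed power is
  ~55–65% and the log transform is the modal but not majority selection —
  a genuine power ceiling of decile-level non-linear MR at this scale,
  not an implementation artifact.
- **Collider bias** — confounded cohorts stratified both ways: raw
  exposure strata are systematically displaced (mean LACE pulled below
  the truth) while residual strata recover θ; a one-sided sign test on
  per-replicate mean absolute bias makes the contrast.

Replicate counts (150/300/40/100 for the studies in the test suite;
slightly fewer in the acceptance script) keep the full validation to a
few minutes per study on one CPU while leaving the Monte-Carlo error
well inside the asserted bands.

## Numerical choices and edge cases

- Quantile strata differ in size by at most one; ties are broken by
  stable input order, so heavily tied values split deterministically. A
  constant stratifying variable is an error, not a silent single stratum.
- Missing dosages are mean-imputed per variant (standard GRS practice,
  keeps n constant); palindromic (A/T, C/G) variants are dropped during
  harmonization with a logged count rather than frequency-inferred.
- LD clumping (greedy, descending |weight|/SE, retain if r² < threshold
  with everything already retained) is provided for completeness; input
  weight tables are normally pre-clumped.
- A perfect first-stage fit reports SE 0 with a warning; a zero β_GX is
  an error (the ratio is undefined).
- FP fits reject singular bases (condition number > 1e12) naming the
  offending powers; model-selection ties are broken toward the linear
  power, then lexicographically.
- p-values are floored at the smallest positive double rather than
  reported as 0.
- All output tables are written with 12-significant-digit floats;
  re-running an identical configuration yields byte-identical files.

## Known limitations

- The one-sample covariance between β_GY and β_GX is ignored; with a
  strong instrument the effect is second-order, but the Fieller option is
  preferable near the weak-instrument regime.
- The chi-squared(1) reference for the non-linearity test does not
  account for power selection (use the permutation option when
  calibration matters).
- Stratum LACEs share the full-cohort β_GX denominator and are therefore
  weakly positively correlated; Cochran's Q and the trend test treat them
  as independent.
- No doubly-ranked stratification, no spline or piecewise alternatives,
  no FP degree above 2, no competing-risks modelling.
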