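# Methods

## Admixture model and estimator

Two-way admixture between an African reference population (frequencies
`p_afr`) and a European reference (`p_eur`). An individual with European
proportion `s` has admixed allele frequency `p(s) = s·p_eur + (1−s)·p_afr`
at each marker; genotype dosages follow Hardy–Weinberg proportions
`(1−p)², 2p(1−p), p²` with markers treated as independent (no linkage
disequilibrium modelling). The per-individual log-likelihood is the sum of
log genotype probabilities over non-missing markers; missing genotypes are
simply omitted from the product and the number of markers used is
recorded.

Estimation: a 101-point grid scan over [0, 1] followed by bounded scalar
minimisation (tolerance 1e-7) inside the best grid cell; ties on the grid
break toward the smaller `s`. The standard error is the inverse square
root of the negative numerical second derivative (central differences,
h = 1e-4) at interior optima; boundary estimates (within 1e-4 of 0 or 1)
are snapped to the boundary with an undefined SE and a `boundary` flag. A
likelihood that is flat to 1e-10 across the grid (all marker frequencies
equal in the two references) returns `s = 0.5` with a `non-identifiable`
flag rather than an error, so degenerate panels do not abort cohort runs.

Reference frequencies are clamped to `[eps, 1−eps]` (default
`eps = 0.001`) before estimation; without clamping, a pseudo-ancestral
fixed difference would contribute `log 0` for a discordant genotype.

The flat-prior posterior mean `∫ s L(s) ds / ∫ L(s) ds` (uniform grid,
log-space with max subtraction, trapezoidal quadrature) serves as an
estimator that shares the likelihood but not the optimisation path; on
informative panels it and the MLE correlate above 0.99, which is the
agreement level classically reported between likelihood-based and
MCMC-based global-ancestry programs. The theoretical benchmark for
estimator precision is the expected information
`I(s) = Σᵢ 2 (p_eur,i − p_afr,i)² / (pᵢ(s)(1−pᵢ(s)))` evaluated at the
generating truth; the cohort RMSE of the MLE sits within a few percent of
`mean(I^{-1/2})` at the default panel scale.

## Synthetic cohort

The generator is the exact generative twin of the likelihood: dosages are
`Binomial(2, p(s))` draws, with a configurable missing rate.

* **Panel.** `p_afr ~ U(0.05, 0.95)`; the European frequency sits a
  differential `|δ| ~ N(delta_mean, 0.05)` away in a randomly chosen
  feasible direction (clipped into `[eps, 1−eps]`). Default
  `delta_mean = 0.4`, typical of genome-wide AIM panels selected for
  African/European contrast; 1447 markers by default.
* **True ancestry.** `s ~ Beta(4.6711, 23.4748)`, shapes obtained by
  quantile matching (shipped as constants; `calibrate_beta_shapes()`
  re-runs the matching) so that the median is 0.158 and the
  interquartile range 0.093 — the study-scale PEA distribution. The
  published mean ± SD on the percent scale (17.3 ± 8.1) is in mild
  tension with that median/IQR; the generator calibrates to the
  median/IQR.
* **Phenotypes.** Covariates co-vary through one latent adiposity factor
  `z`: BMI is lognormal by sex (means 33.0/29.5, SDs 7.4/5.7, a common
  meanlog shift calibrated so obesity prevalence is 766/1439), waist is
  linear in BMI, fasting insulin is tied to `z` so HOMA-IR has mean ≈ 3.5
  and SD ≈ 2.3, HDL loads negatively and triglycerides/CRP positively on
  `z`. Sex is ≈62% female; age is truncated normal 48 ± 12 (≥ 21);
  insulin is missing for an exact count of round(0.173·n) individuals,
  mirroring an assay shortfall of 249/1439. Classification flags
  (obesity, upper-quartile insulin resistance, diabetes) are computed
  from the *rounded* shipped values via the same functions the analysis
  uses, so re-derivation from the written CSV reproduces them exactly.
* **Outcome.** log-adiponectin = intercept + sex effect + stratum-slope ×
  s + effects of HOMA-IR (−0.09), HDL (+0.012), waist (−0.01), CRP
  (−0.02) + N(0, 0.55) noise. The resulting adjusted-correlation sign
  structure matches the field's: adiponectin negative with HOMA-IR and
  adiposity, positive with HDL, weakly positive with ancestry; women have
  higher adiponectin. The stratified PEA coefficient's standard error at
  the default scale (~0.26 in the non-obese stratum) matches the
  study-scale precision.

### Stratum slopes and the consistency constraint

The configured targets are per-analysis-stratum slopes: 0.62 (non-obese),
0 (obese), 0.74 (insulin-sensitive), 0 (insulin-resistant) by default.
Because every individual belongs to one obesity stratum *and* one IR
stratum, and true ancestry is independent of both, the four stratum-level
slopes are not free: both stratifications must aggregate to the same
cohort-level slope (law of total covariance), i.e.

    n_nonobese·β_nonobese + n_obese·β_obese
        = n_nonIR·β_nonIR + n_IR·β_IR.

The default targets violate this identity — they are calibrated to
partial coefficients from four differently-adjusted models, which no
single linear-in-s generative mechanism can reproduce simultaneously. The
generator therefore solves for slopes on the four obesity×IR cells by
least squares against the configured targets (a rank-3 system) and
records the realized per-stratum generating slopes — the count-weighted
cell averages, which are what a stratified regression is unbiased for —
in `truth.json`. Setting a stratum target to `None` drops its constraint;
with one whole dimension unconstrained the remaining targets are met
exactly, and an all-zero configuration is exactly consistent (all cell
slopes 0), which is how null calibration studies are run. Coverage claims
are always assessed against the realized generating slopes.

The insulin-sensitive stratum is defined as *not flagged* insulin
resistant, so participants without a HOMA-IR measurement belong to it —
matching how the stratum is sized in practice (1141 = 1439 − 298).

## Derived variables

BMI = weight/height² (kg/m²); obesity ⇔ BMI ≥ 30 (inclusive). HOMA-IR =
insulin (µU/mL) × glucose (mmol/L) / 22.5; glucose supplied in mg/dL is
divided by 18.016 first, and units are declared in configuration, never
guessed. Insulin resistance flags average ranks above 0.75·n among the n
non-missing HOMA-IR values — the top quartile by rank, deterministic
under ties, flagging exactly 298 of 1190 distinct values; the quartile is
computed on all non-missing values pooled (not by sex, not after
exclusions). Diabetes ⇔ glucose ≥ 7.0 mmol/L or glucose-lowering
medication. Adiponectin is analysed as its natural log. No imputation
anywhere: individuals missing a model's variable are excluded from that
model (complete-case within each variable set).

## Association analysis

* Sex differences: classical equal-variance Student t (continuous),
  uncorrected chi-square (categorical).
* Adjusted correlations: residualise both variables on intercept + age +
  sex by OLS, correlate the residuals; p from
  `t = r·sqrt((n−2−k)/(1−r²))` with `n−2−k` df.
* Effect modification: Gaussian-ML nested linear models with and without
  the exposure×modifier product; LRT = 2·Δloglik against χ²₁. A
  constant product column returns LRT = 0 (identical models); any other
  rank deficiency is an error naming the collinear term.
* Stepwise: forward-only from intercept, adding the candidate with the
  smallest partial-F p-value while it is ≤ 0.05 (the study's stated
  threshold; no removal step, ties broken by candidate order). The
  exposure is an ordinary candidate but is always reported: when
  unselected, its entry coefficient/SE/p into the final model is given.
  Per-stratum candidate rosters exclude the stratifying variable's own
  scale (no BMI in obesity strata, no HOMA-IR in IR strata). Strata below
  50 observations are skipped.

## Spline linearity analysis

`log-adiponectin ~ covariates + f(PEA)` with `f` a natural cubic
regression spline: knots at k = 10 quantiles of PEA, coefficients the
function values at the knots, curvature penalty the exact integrated
squared second derivative (`K = DᵀW⁻¹D` from the classical banded
construction), sum-to-zero constraint against the intercept, smoothing
parameter by GCV over a wide scale-free log grid with inflation factor
1.4 (the customary guard against undersmoothing). With the penalty driven
to infinity the smooth collapses exactly to a straight line (edf → 1);
fitted values are invariant to affine rescaling of the exposure.

Two comparisons are reported. Because an F statistic referred to the
data-selected effective degrees of freedom of a penalized fit is
anticonservative (and degenerates entirely as edf → 1), the p-values use
exact F tests between nested *unpenalized* models: covariates-only vs the
full spline basis (`p_deviance`, df = k−2 after the constraint) and
covariates + linear PEA vs the full basis (`p_nonlinearity`, df = k−3).
The penalized fit supplies the reported deviances, the curve, its
pointwise band, and the edf. The compound rule declares non-linearity
when `p_nonlinearity ≤ 0.05` **and** edf > 3. Under linear truth the rule
flags ≈ 1–7% of replicates; under a strong cubic signal it detects
essentially always; under no signal `p_deviance` rejects at the nominal
5%.

## What the tests do and do not show

The synthetic cohort shares the analysis's genotype model exactly, has no
linkage disequilibrium, no genotyping error, no family structure, and
covariate dependence through a single latent factor; passing tests
demonstrate the correctness and calibration of the estimators and
procedures under the stated model, not robustness to real-data violations
of it (LD between AIMs, assay error, population substructure). Reported
study-scale coefficients depend on participant data that is not bundled;
the generator reproduces their magnitudes and precision as calibration
targets, not their values.

Problem sizes used by the evaluation studies: 500 × 300 for estimator
agreement; 1439 × 1447 for full-scale recovery; 1000 replicates for
interaction and stepwise calibration; 200 replicates per truth for the
spline rule; 500 replicates for stratified coverage. All studies are
seeded and re-run from scratch by `scripts/acceptance.py`.

## Known limitations

* Global ancestry only; no local ancestry, no three-way admixture.
* The independence-across-markers assumption is inherited from the
  product likelihood; LD pruning of panels is the user's responsibility.
* The SE from observed information is undefined at boundary estimates.
* Stepwise selection p-values are nominal, not selection-adjusted; the
  always-reported exposure coefficient is the honest summary.
* The GCV-selected edf is a point estimate; the >3 rule inherits its
  variability.
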