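# admixpheno

Estimation of individual two-way admixture proportions from
ancestry-informative markers (AIMs), and adjusted association analysis of
admixture with cardio-metabolic phenotypes — written for population
geneticists and cardiovascular epidemiologists studying admixed cohorts
(the motivating setting is an African-American cohort where plasma
adiponectin is analysed against each participant's proportion of European
ancestry, PEA).

## The model

For a cohort admixed between two ancestral populations with counted-allele
frequencies *p₁ᵢ* (African) and *p₂ᵢ* (European) at marker *i*, an
individual with European proportion *s* ∈ [0, 1] carries the admixed
allele frequency

    pᵢ(s) = s · p₂ᵢ + (1 − s) · p₁ᵢ

and, under Hardy–Weinberg proportions with independent markers, dosage
*Gᵢ* ∈ {0, 1, 2} has likelihood

    L(s) = ∏ᵢ Pr(Gᵢ | pᵢ(s)),    log L(s) = Σᵢ log Pr(Gᵢ | pᵢ(s)).

`admixpheno` maximises log *L* per individual (grid scan plus bounded
refinement), reports a standard error from the observed information, and
cross-checks the MLE against a flat-prior posterior-mean estimator (the
two agree with Pearson r > 0.99 on informative panels, the level of
agreement classically reported between likelihood- and MCMC-based global
ancestry methods).

Downstream, the package derives BMI, HOMA-IR (insulin × glucose / 22.5),
obesity (BMI ≥ 30), insulin resistance (upper quartile of HOMA-IR),
and diabetes (glucose ≥ 7.0 mmol/L or treatment) flags; computes age- and
sex-adjusted Pearson correlations; tests effect modification by
likelihood-ratio comparison of nested linear models; fits forward
stepwise regressions of log-adiponectin on PEA within obesity and
insulin-resistance strata (entry at P ≤ 0.05, PEA always reported); and
tests linearity of the PEA–adiponectin relation with a penalized cubic
regression spline inside an additive model (non-linear ⇔ significant
smooth-vs-linear comparison AND estimated degrees of freedom > 3).

A seeded synthetic-cohort generator with the same genotype model and a
calibrated phenotype structure makes every stage testable without any
external data.

## Worked example

Run the full pipeline on a synthetic cohort of 1439 individuals × 1447
AIMs (the default configuration):

```bash
admixpheno run-all --out-dir demo --seed 1
```

which ends by printing the ancestry summary

```json
{"n": 1439, "median": 0.1602, "iqr": 0.0911, "mean": 0.1660, "sd": 0.0700}
```

— the estimated PEA distribution (median ≈ 16%, IQR ≈ 9%) recovered from
genotypes alone, matching the generator's Beta-distributed truth.  The run
report (`demo/report.json`) records, per stage, counts that always
reconcile (retained + excluded = input), e.g. the derivation stage:

```json
{"input": 1439, "retained": 1439, "excluded": 0,
 "n_obese": 790, "n_insulin_resistant": 298, "n_diabetic": 211}
```

`demo/table3.csv` holds the stratified stepwise models.  The PEA rows for
this seed are

```
    stratum  selected     beta       se  beta_if_added        p    n
  non-obese     False      NaN      NaN          0.614 0.059511  530
      obese     False      NaN      NaN          0.264 0.405233  660
     non-IR     False      NaN      NaN          0.391 0.100457 1141
         IR     False      NaN      NaN          0.258 0.598905  298
no-diabetes      True    0.718    0.249            NaN 0.003975 1009
```

PEA is reported in every stratum whether or not the stepwise procedure
selected it: an unselected row gives the coefficient and p-value PEA would
take on entry into the final model (the tabular "dash" convention).  Here
the non-obese estimate (0.61, p = 0.06) sits right at the entry threshold
— at the generator's calibrated effect sizes the power of this stratum is
moderate, so selection varies across replicates — while the
diabetes-free sensitivity model selects PEA (β = 0.72 ± 0.25, p = 0.004).
`demo/spline_fits.csv` and `demo/spline_fits.png` show that all four
stratum smooths are declared linear, as generated.

Individual stages are available as subcommands (`simulate`,
`select-aims`, `estimate-ancestry`, `derive`, `associate`, `spline`), all
reading and writing plain TSV/CSV with documented headers.

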