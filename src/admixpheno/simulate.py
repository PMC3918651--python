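"""Synthetic two-way admixed cohort generator.

Generates the three inputs the analysis pipeline consumes — an
ancestry-informative marker (AIM) panel, a genotype dosage matrix, and a
cardio-metabolic phenotype table — with the statistical structure the
downstream analysis assumes:

* true individual European ancestry proportions are Beta distributed,
  with default shapes quantile-matched to a median of 15.8% and an
  interquartile range of 9.3%;
* genotype dosages are Binomial(2, p(s)) draws at each marker, the exact
  generative twin of the Hardy-Weinberg product likelihood that the
  estimator maximises;
* log-adiponectin depends linearly on ancestry with a slope that differs
  by obesity and insulin-resistance stratum (by default: positive among
  the non-obese and the insulin sensitive, zero otherwise), plus additive
  covariate effects and Gaussian noise.

Because an individual belongs simultaneously to an obesity stratum and an
insulin-resistance stratum, the per-stratum target slopes cannot be applied
directly per individual.  The generator instead solves a small linear
system for slopes on the four obesity-by-IR cells such that the weighted
average within each analysis stratum equals its configured target; true
ancestry is drawn independently of stratum membership, so each stratified
regression is unbiased for its configured slope by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ancestry import MISSING, AIMPanel, GenotypeMatrix
from .phenotypes import (
    MGDL_PER_MMOL,
    classify_insulin_resistance,
    compute_bmi,
)

__all__ = [
    "PEA_BETA_A",
    "PEA_BETA_B",
    "SimulationConfig",
    "calibrate_beta_shapes",
    "simulate_panel",
    "simulate_true_pea",
    "simulate_genotypes",
    "simulate_phenotypes",
]

#: Beta shapes for the true European ancestry proportion, quantile-matched
#: (see :func:`calibrate_beta_shapes`) to median 0.158 and IQR 0.093.
PEA_BETA_A = 4.671090703510916
PEA_BETA_B = 23.47475691128939

#: common shift applied to the sex-specific log-BMI means so that the
#: obesity prevalence is 766/1439 (see :func:`calibrate_bmi_shift`)
_BMI_SHIFT = 0.00962353978896792

# sex-specific lognormal BMI parameters matched to mean 33.0 sd 7.4 (women)
# and 29.5 sd 5.7 (men) before the prevalence shift
_BMI_PARAMS = {"F": (3.471976943072506, 0.2214977128278038),
               "M": (3.3660632352753996, 0.19145249055770902)}


def calibrate_beta_shapes(median: float = 0.158, iqr: float = 0.093):
    """Solve for Beta shapes whose median and IQR match the targets.

    This is the matching procedure behind the shipped ``PEA_BETA_A/B``
    constants; it is exposed so the calibration can be re-run.
    """
    def resid(x):
        a, b = np.exp(x)
        d = stats.beta(a, b)
        q1, med, q3 = d.ppf([0.25, 0.5, 0.75])
        return [med - median, (q3 - q1) - iqr]
    sol = optimize.root(resid, np.log([3.0, 15.0]))
    if not sol.success:
        raise RuntimeError("beta-shape calibration failed to converge")
    return tuple(np.exp(sol.x))


def calibrate_bmi_shift(prevalence: float = 766 / 1439, p_female: float = 0.62):
    """Common log-BMI shift giving the target obesity prevalence."""
    (muF, sgF), (muM, sgM) = _BMI_PARAMS["F"], _BMI_PARAMS["M"]
    def prev(d):
        pf = 1 - stats.norm.cdf((np.log(30) - (muF - d)) / sgF)
        pm = 1 - stats.norm.cdf((np.log(30) - (muM - d)) / sgM)
        return p_female * pf + (1 - p_female) * pm
    return optimize.brentq(lambda d: prev(d) - prevalence, -0.5, 0.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    The stratum slopes are on the log-adiponectin scale per unit ancestry
    proportion; the defaults are the study-scale calibration (a positive
    association confined to the non-obese and insulin-sensitive strata).
    """

    n_individuals: int = 1439
    n_markers: int = 1447
    delta_mean: float = 0.4
    pea_beta_a: float = PEA_BETA_A
    pea_beta_b: float = PEA_BETA_B
    #: per-stratum target slopes of log-adiponectin on ancestry; ``None``
    #: leaves a stratum unconstrained.  The four targets are linearly
    #: dependent (both stratifications aggregate to the cohort slope), so
    #: inconsistent targets are projected onto the consistent subspace; the
    #: realized per-stratum generating slopes are recorded in the truth dict.
    beta_pea_nonobese: float | None = 0.62
    beta_pea_obese: float | None = 0.0
    beta_pea_nonir: float | None = 0.74
    beta_pea_ir: float | None = 0.0
    #: additive effects on log-adiponectin (units: per unit of covariate)
    beta_male: float = -0.28
    beta_homa: float = -0.09
    beta_hdl: float = 0.012
    beta_waist: float = -0.01
    beta_crp: float = -0.02
    intercept: float = 2.13
    noise_sd: float = 0.55
    p_female: float = 0.62
    genotype_missing_rate: float = 0.01
    insulin_missing_rate: float = 249 / 1439
    eps: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_markers < 1:
            raise ValueError("counts must be >= 1")
        for name in ("genotype_missing_rate", "insulin_missing_rate", "p_female"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.pea_beta_a <= 0 or self.pea_beta_b <= 0:
            raise ValueError("Beta shapes must be positive")


def simulate_panel(
    n_markers: int, delta_mean: float, seed: int, eps: float = 0.001
) -> AIMPanel:
    """Draw an AIM panel with a target mean allele-frequency differential.

    African frequencies are uniform on [0.05, 0.95]; the European frequency
    sits a differential away in a randomly chosen feasible direction, so the
    realised mean differential tracks *delta_mean* closely for panels of a
    few hundred markers or more.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0 <= delta_mean < 0.9:
        raise ValueError("delta_mean must lie in [0, 0.9)")
    rng = np.random.default_rng(seed)
    p_afr = rng.uniform(0.05, 0.95, n_markers)
    delta = np.abs(rng.normal(delta_mean, 0.05, n_markers)) if delta_mean > 0 \
        else np.zeros(n_markers)
    up_ok = p_afr + delta <= 1 - eps
    dn_ok = p_afr - delta >= eps
    go_up = rng.random(n_markers) < 0.5
    go_up = np.where(up_ok & dn_ok, go_up, up_ok)
    p_eur = np.where(go_up, p_afr + delta, p_afr - delta)
    p_eur = np.clip(p_eur, eps, 1 - eps)
    marker_id = np.array([f"AIM{i:05d}" for i in range(n_markers)], dtype=object)
    alleles = rng.choice(np.array(["A", "C", "G", "T"], dtype=object), n_markers)
    return AIMPanel(marker_id, alleles, p_afr, p_eur, eps=eps)


def simulate_true_pea(
    n: int, beta_a: float = PEA_BETA_A, beta_b: float = PEA_BETA_B,
    seed: int = 0,
) -> np.ndarray:
    """Draw true individual European ancestry proportions, i.i.d. Beta."""
    if beta_a <= 0 or beta_b <= 0:
        raise ValueError("Beta shapes must be positive")
    rng = np.random.default_rng(seed)
    return rng.beta(beta_a, beta_b, n)


def simulate_genotypes(
    panel: AIMPanel, s_true: np.ndarray, missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw Binomial(2, p(s)) dosages at every marker for every individual."""
    s = np.asarray(s_true, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("true ancestry proportions must lie in [0, 1]")
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = s[:, None] * panel.p_eur[None, :] + (1 - s[:, None]) * panel.p_afr[None, :]
    dosage = rng.binomial(2, p).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    ids = np.array([f"IND{i:05d}" for i in range(len(s))], dtype=object)
    return GenotypeMatrix(ids, dosage, panel.marker_id)


def _solve_cell_slopes(config: SimulationConfig, cell: np.ndarray) -> np.ndarray:
    """Slopes for the four obesity-by-IR cells hitting the stratum targets.

    ``cell`` codes 0 = non-obese/non-IR, 1 = non-obese/IR, 2 = obese/non-IR,
    3 = obese/IR.  Within each analysis stratum the weighted average of cell
    slopes (weights = empirical cell shares) must equal the configured
    stratum slope; that is a 4x4 linear system, solved in the least-squares
    sense so degenerate stratum compositions stay well defined.
    """
    counts = np.bincount(cell, minlength=4).astype(float)
    t_no, t_ob = config.beta_pea_nonobese, config.beta_pea_obese
    t_ni, t_ir = config.beta_pea_nonir, config.beta_pea_ir
    # one stratification unconstrained: slope uniform within each stratum
    # of the other (the natural single-dimension generative model)
    if t_ni is None and t_ir is None and t_no is not None and t_ob is not None:
        return np.array([t_no, t_no, t_ob, t_ob], dtype=float)
    if t_no is None and t_ob is None and t_ni is not None and t_ir is not None:
        return np.array([t_ni, t_ir, t_ni, t_ir], dtype=float)
    rows, rhs = [], []
    for cells, target in (
        ((0, 1), t_no), ((2, 3), t_ob), ((0, 2), t_ni), ((1, 3), t_ir),
    ):
        tot = counts[list(cells)].sum()
        if tot == 0 or target is None:
            continue
        row = np.zeros(4)
        for c in cells:
            row[c] = counts[c] / tot
        rows.append(row)
        rhs.append(target)
    if not rows:
        return np.zeros(4)
    slopes, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return slopes


def realized_stratum_slopes(cell_slopes: np.ndarray, cell: np.ndarray) -> dict:
    """Count-weighted generating slope within each analysis stratum.

    With true ancestry independent of stratum membership the within-stratum
    regression slope equals the count-weighted average of the cell slopes,
    so these are the generating values a stratified fit is unbiased for.
    The four configured targets obey a law-of-total-covariance identity
    (both stratifications aggregate to the same cohort-level slope), so
    when the configuration is inconsistent the realized values are the
    least-squares projection onto the consistent subspace, not the targets.
    """
    counts = np.bincount(cell, minlength=4).astype(float)
    out = {}
    for name, cells in (("nonobese", (0, 1)), ("obese", (2, 3)),
                        ("nonir", (0, 2)), ("ir", (1, 3))):
        tot = counts[list(cells)].sum()
        out[name] = float(sum(counts[c] * cell_slopes[c] for c in cells) / tot) \
            if tot else np.nan
    return out


def simulate_phenotypes(
    s_true: np.ndarray, config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the cardio-metabolic phenotype table for a cohort.

    Covariates co-vary through a single latent adiposity factor with signs
    matching the field's adjusted-correlation structure (adiponectin
    negative with HOMA-IR and waist, positive with HDL); true ancestry is
    independent of every covariate so adjusted regressions stay unbiased.

    Returns the table and a ``truth`` dict recording every generating
    parameter, the solved cell slopes, and the true ancestry values.
    """
    config = config or SimulationConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    s = np.asarray(s_true, dtype=float)
    n = len(s)

    female = rng.random(n) < config.p_female
    age = stats.truncnorm.rvs((21 - 48) / 12, np.inf, loc=48, scale=12,
                              size=n, random_state=rng)
    z = rng.normal(size=n)  # latent adiposity factor

    mu = np.where(female, _BMI_PARAMS["F"][0], _BMI_PARAMS["M"][0]) - _BMI_SHIFT
    sg = np.where(female, _BMI_PARAMS["F"][1], _BMI_PARAMS["M"][1])
    rho = 0.7
    bmi = np.exp(mu + sg * (rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)))
    height = np.where(female, rng.normal(1.62, 0.07, n), rng.normal(1.76, 0.08, n))
    weight = bmi * height**2
    waist = 39.0 + 1.9 * bmi + rng.normal(0, 8.0, n)

    glucose_mgdl = np.exp(rng.normal(4.52, 0.29, n) + 0.05 * z)  # ~96 +/- 29
    ln_homa = 1.073 + 0.599 * (0.6 * z + 0.8 * rng.normal(size=n))
    homa_true = np.exp(ln_homa)
    insulin = homa_true * 22.5 / (glucose_mgdl / MGDL_PER_MMOL)

    hdl = np.where(female, 53.6, 45.5) - 4.0 * z + \
        np.where(female, 13.2, 10.8) * rng.normal(size=n)
    hdl = np.clip(hdl, 15.0, None)
    tg = np.exp(np.where(female, 4.37, 4.42) + 0.55 * (0.4 * z + 0.92 * rng.normal(size=n)))
    crp = np.exp(1.014 + 1.072 * (0.3 * z + 0.954 * rng.normal(size=n)))
    sbp = rng.normal(122, 16.5, n) + 3.0 * z
    dbp = rng.normal(79, 10.0, n) + 1.5 * z
    activity = np.clip(np.round(rng.normal(8.9, 2.4, n)), 0, 24)
    alcohol = (rng.random(n) < np.where(female, 0.50, 0.66)).astype(int)
    education = (rng.random(n) < 0.37).astype(int)
    meds = ((glucose_mgdl >= 126) & (rng.random(n) < 0.10)) | (rng.random(n) < 0.02)

    # insulin missing for an exact count of individuals, as in a designed
    # assay shortfall; HOMA-IR and the IR flag are then undefined for them
    n_miss = int(round(config.insulin_missing_rate * n))
    insulin_obs = insulin.copy()
    if n_miss:
        insulin_obs[rng.choice(n, size=n_miss, replace=False)] = np.nan

    # round measurements to shipped precision BEFORE classifying, so that
    # re-derivation from the written table reproduces the flags exactly
    weight_r = np.round(weight, 2)
    height_r = np.round(height, 3)
    waist_r = np.round(waist, 1)
    hdl_r = np.round(hdl, 1)
    glucose_r = np.round(glucose_mgdl, 1)
    insulin_r = np.round(insulin_obs, 2)
    crp_r = np.round(crp, 2)

    obese = compute_bmi(weight_r, height_r) >= 30.0
    homa_all = np.round(insulin, 2) * (glucose_r / MGDL_PER_MMOL) / 22.5
    homa_obs = np.where(np.isnan(insulin_r), np.nan, homa_all)
    if np.isfinite(homa_obs).sum() >= 4:
        ir_flag = classify_insulin_resistance(homa_obs)
    else:
        ir_flag = np.full(n, np.nan)
    ir = ir_flag == 1  # missing HOMA-IR counts as not flagged, as analysed
    cell = obese.astype(int) * 2 + ir.astype(int)
    cell_slopes = _solve_cell_slopes(config, cell)
    slope = cell_slopes[cell]

    log_adipo = (
        config.intercept
        + config.beta_male * (~female)
        + slope * s
        + config.beta_homa * homa_all
        + config.beta_hdl * hdl_r
        + config.beta_waist * waist_r
        + config.beta_crp * crp_r
        + rng.normal(0, config.noise_sd, n)
    )

    table = pd.DataFrame({
        "individual_id": [f"IND{i:05d}" for i in range(n)],
        "age": np.round(age, 1),
        "sex": np.where(female, "F", "M"),
        "adiponectin": np.exp(log_adipo),
        "weight": weight_r,
        "height": height_r,
        "waist": waist_r,
        "triglycerides": np.round(tg, 1),
        "hdl": hdl_r,
        "glucose": glucose_r,
        "insulin": insulin_r,
        "sbp": np.round(sbp, 1),
        "dbp": np.round(dbp, 1),
        "activity": activity.astype(int),
        "alcohol": alcohol,
        "crp": crp_r,
        "education": education,
        "diabetes_meds": meds.astype(int),
    })
    truth = {
        "config": asdict(config),
        "seed": seed,
        "cell_slopes": cell_slopes.tolist(),
        "cell_counts": np.bincount(cell, minlength=4).tolist(),
        "stratum_slopes": realized_stratum_slopes(cell_slopes, cell),
        "s_true": s.tolist(),
    }
    return table, truth
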