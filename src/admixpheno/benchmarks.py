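"""Self-contained evaluation studies of the pipeline's statistical claims.

Each function simulates its own inputs with the package's generators, runs
the estimator or test under study, and returns the measured quantity:
estimator agreement, classification counts, optimizer-oracle agreement,
parameter-recovery error, type-I-error calibration of the interaction and
selection procedures, spline decision-rule operating characteristics, and
stratified-coefficient recovery.  They power the acceptance script and the
acceptance test suite; every routine takes an explicit seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ancestry import (
    _grid_loglik_matrix,
    estimate_ancestry,
    estimate_cohort,
    fisher_se,
    posterior_mean_ancestry,
)
from .phenotypes import classify_insulin_resistance, derive
from .simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_panel,
    simulate_phenotypes,
    simulate_true_pea,
)
from .splines import fit_pea_spline
from .stats import interaction_lrt, stepwise_forward, stratified_analysis

__all__ = [
    "cross_estimator_agreement",
    "ir_rule_flag_count",
    "grid_oracle_agreement",
    "cohort_recovery_study",
    "interaction_null_calibration",
    "stepwise_null_calibration",
    "spline_decision_rates",
    "stratified_recovery_study",
]


def _seeded(seed: int, k: int) -> int:
    return int((seed * 1000 + k) % (2**31 - 1))


def cross_estimator_agreement(seed: int, n: int = 500, n_markers: int = 300,
                              delta_mean: float = 0.4) -> dict:
    """Pearson r between the MLE and the flat-prior posterior mean."""
    panel = simulate_panel(n_markers, delta_mean, seed=_seeded(seed, 1))
    s = simulate_true_pea(n, seed=_seeded(seed, 2))
    gm = simulate_genotypes(panel, s, missing_rate=0.01, seed=_seeded(seed, 3))
    mle = np.array([estimate_ancestry(gm.dosage[i], panel).s_hat
                    for i in range(n)])
    pm = np.array([posterior_mean_ancestry(gm.dosage[i], panel)
                   for i in range(n)])
    return {"r": float(np.corrcoef(mle, pm)[0, 1]), "n": n}


def ir_rule_flag_count(seed: int, n: int = 1190) -> dict:
    """Individuals flagged by the upper-quartile rule on n distinct values."""
    rng = np.random.default_rng(_seeded(seed, 4))
    vals = rng.lognormal(1.07, 0.6, n)
    assert len(np.unique(vals)) == n
    flags = classify_insulin_resistance(vals)
    return {"flagged": int(np.nansum(flags)), "n": n}


def grid_oracle_agreement(seed: int, n: int = 120, n_markers: int = 300,
                          grid_n: int = 10_001) -> dict:
    """Max |MLE - exhaustive grid argmax| over simulated individuals."""
    panel = simulate_panel(n_markers, 0.4, seed=_seeded(seed, 5))
    s = simulate_true_pea(n, seed=_seeded(seed, 6))
    gm = simulate_genotypes(panel, s, missing_rate=0.01, seed=_seeded(seed, 7))
    grid = np.linspace(0, 1, grid_n)
    ll = _grid_loglik_matrix(gm.dosage, panel, grid)
    grid_hat = grid[np.argmax(ll, axis=1)]
    mle = np.array([estimate_ancestry(gm.dosage[i], panel).s_hat
                    for i in range(n)])
    return {"max_abs_diff": float(np.max(np.abs(mle - grid_hat))), "n": n}


def cohort_recovery_study(seed: int, n: int = 1439,
                          n_markers: int = 1447) -> dict:
    """Full-scale ancestry recovery against the information-bound oracle."""
    panel = simulate_panel(n_markers, 0.4, seed=_seeded(seed, 8))
    s = simulate_true_pea(n, seed=_seeded(seed, 9))
    gm = simulate_genotypes(panel, s, missing_rate=0.01, seed=_seeded(seed, 10))
    ests, _ = estimate_cohort(gm, panel)
    s_hat = np.array([e.s_hat for e in ests])
    rmse = float(np.sqrt(np.mean((s_hat - s) ** 2)))
    se_bar = float(fisher_se(panel, s).mean())
    q1t, q3t = np.percentile(s, [25, 75])
    q1e, q3e = np.percentile(s_hat, [25, 75])
    return {
        "rmse": rmse,
        "mean_theoretical_se": se_bar,
        "rmse_over_se": rmse / se_bar,
        "median_hat": float(np.median(s_hat)),
        "median_true": float(np.median(s)),
        "median_abs_error": float(abs(np.median(s_hat) - np.median(s))),
        "iqr_hat": float(q3e - q1e),
        "iqr_true": float(q3t - q1t),
        "iqr_abs_error": float(abs((q3e - q1e) - (q3t - q1t))),
        "n": n,
    }


def interaction_null_calibration(seed: int, n: int = 800,
                                 n_reps: int = 1000,
                                 alpha: float = 0.05) -> dict:
    """Rejection rate of the exposure-by-modifier LRT when no interaction
    exists (constant exposure effect, correlated covariates present)."""
    rejections = 0
    for i in range(n_reps):
        rng = np.random.default_rng(_seeded(seed, 11) + i)
        d = pd.DataFrame({
            "pea": rng.beta(4.67, 23.47, n),
            "m": rng.normal(size=n),
            "c": rng.normal(size=n),
            "sex": "F",
        })
        d["y"] = (1.0 + 0.5 * d["pea"] + 0.3 * d["m"] + 0.2 * d["c"]
                  + rng.normal(0, 0.5, n))
        res = interaction_lrt("y", "pea", "m", ["c"], d)
        rejections += res.p <= alpha
    return {"rejection_rate": rejections / n_reps, "n": n_reps}


def stepwise_null_calibration(seed: int, n: int = 300, n_cand: int = 6,
                              n_reps: int = 1000,
                              alpha: float = 0.05) -> dict:
    """Per-candidate entry rate when every candidate is pure noise."""
    names = [f"c{j}" for j in range(n_cand)]
    counts = dict.fromkeys(names, 0)
    for i in range(n_reps):
        rng = np.random.default_rng(_seeded(seed, 12) + i)
        d = pd.DataFrame({nm: rng.normal(size=n) for nm in names})
        d["y"] = rng.normal(size=n)
        res = stepwise_forward("y", d, names, alpha_enter=alpha)
        for t in res.terms:
            if t.selected:
                counts[t.name] += 1
    rates = {nm: c / n_reps for nm, c in counts.items()}
    return {"entry_rates": rates,
            "mean_entry_rate": float(np.mean(list(rates.values()))),
            "max_entry_rate": float(np.max(list(rates.values()))),
            "min_entry_rate": float(np.min(list(rates.values()))),
            "n": n_reps}


def _spline_frame(kind: str, n: int, rng) -> pd.DataFrame:
    x = rng.beta(4.67, 23.47, n)
    z = rng.normal(size=n)
    if kind == "lin":
        y = 2.0 + 3.0 * x + 0.3 * z + rng.normal(0, 0.5, n)
    elif kind == "cub":
        xc = (x - x.mean()) / x.std()
        y = 2.0 + 0.5 * xc ** 3 + 0.3 * z + rng.normal(0, 0.5, n)
    else:
        y = 2.0 + 0.3 * z + rng.normal(0, 0.5, n)
    return pd.DataFrame({"log_adiponectin": y, "pea": x, "z": z})


def spline_decision_rates(seed: int, n: int = 1000,
                          n_reps: int = 200) -> dict:
    """Operating characteristics of the compound linearity rule.

    Linear truth should essentially never be flagged non-linear; a strong
    cubic signal should be flagged (edf > 3 with a significant
    smooth-vs-linear comparison) nearly always.
    """
    lin_flags, cub_hits = 0, 0
    for i in range(n_reps):
        rng = np.random.default_rng(_seeded(seed, 13) + i)
        f_lin = fit_pea_spline(_spline_frame("lin", n, rng), ["z"])
        lin_flags += f_lin.nonlinear_flag
        rng = np.random.default_rng(_seeded(seed, 14) + i)
        f_cub = fit_pea_spline(_spline_frame("cub", n, rng), ["z"])
        cub_hits += (f_cub.edf > 3.0) and (f_cub.p_nonlinearity < 0.05)
    return {
        "linear_truth_flag_false_rate": 1.0 - lin_flags / n_reps,
        "cubic_truth_detection_rate": cub_hits / n_reps,
        "n": n_reps,
    }


def spline_null_calibration(seed: int, n: int = 1000,
                            n_reps: int = 400, alpha: float = 0.05) -> dict:
    """Rejection rate of the ancestry-term deviance test when the outcome
    is independent of ancestry."""
    rejections = 0
    for i in range(n_reps):
        rng = np.random.default_rng(_seeded(seed, 15) + i)
        f = fit_pea_spline(_spline_frame("null", n, rng), ["z"])
        rejections += f.p_deviance <= alpha
    return {"rejection_rate": rejections / n_reps, "n": n_reps}


def stratified_recovery_study(seed: int, n_reps: int = 500,
                              null_config: bool = False) -> dict:
    """Coverage of the stratified stepwise models' 95% CIs for the
    generating per-stratum slopes, and the exposure selection rates.

    With ``null_config`` all four stratum targets are 0 (a consistent
    configuration with every cell slope exactly zero), so the selection
    rate estimates the procedure's type-I error.
    """
    if null_config:
        cfg = SimulationConfig(beta_pea_nonobese=0.0, beta_pea_obese=0.0,
                               beta_pea_nonir=0.0, beta_pea_ir=0.0)
    else:
        cfg = SimulationConfig()
    key = {"non-obese": "nonobese", "obese": "obese",
           "non-IR": "nonir", "IR": "ir"}
    cover = dict.fromkeys(key, 0)
    select = dict.fromkeys(key, 0)
    totals = dict.fromkeys(key, 0)
    for i in range(n_reps):
        s = simulate_true_pea(cfg.n_individuals, seed=_seeded(seed, 16) + 2 * i)
        tab, truth = simulate_phenotypes(s, cfg,
                                         seed=_seeded(seed, 16) + 2 * i + 1)
        tab["pea"] = s
        d = derive(tab, glucose_units="mg/dL")
        for r in stratified_analysis(d, sensitivity_no_diabetes=False):
            t = r.term("pea")
            gen = truth["stratum_slopes"][key[r.stratum]]
            totals[r.stratum] += 1
            cover[r.stratum] += abs(t.beta - gen) <= 1.96 * t.se
            select[r.stratum] += t.selected
    return {
        "coverage": {k: cover[k] / totals[k] for k in totals},
        "selection_rate": {k: select[k] / totals[k] for k in totals},
        "generating_slopes": truth["stratum_slopes"],
        "n": n_reps,
    }
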