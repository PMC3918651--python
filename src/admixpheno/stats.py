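"""Adjusted correlation, effect-modification and stepwise regression analysis.

The analysis surfaces mirror a classical epidemiological workflow for a
single continuous outcome (log adiponectin) and a focal exposure (the
individual proportion of European ancestry, PEA):

* descriptive sex-difference tests (Student t / chi-square),
* age- and sex-adjusted Pearson correlations by OLS residualisation,
* likelihood-ratio tests of effect modification (exposure x modifier
  interaction in nested Gaussian linear models),
* forward stepwise linear regression within strata, with the exposure
  always reported whether or not it is selected.

Entry significance is P <= 0.05 throughout, forward-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AdjustedCorrelation",
    "InteractionTest",
    "RegressionResult",
    "sex_difference_table",
    "adjusted_pearson",
    "interaction_lrt",
    "stepwise_forward",
    "stratified_analysis",
    "DEFAULT_CANDIDATES",
]

#: candidate covariate roster for the stratified models; BMI and waist swap
#: in/out depending on the stratifying variable (no BMI when stratifying by
#: obesity, no HOMA-IR when stratifying by insulin resistance)
DEFAULT_CANDIDATES = {
    "obesity": ["age", "sex_male", "waist", "triglycerides", "hdl", "homa_ir",
                "sbp", "dbp", "activity", "alcohol", "crp", "education"],
    "ir": ["age", "sex_male", "bmi", "waist", "triglycerides", "hdl",
           "sbp", "dbp", "activity", "alcohol", "crp", "education"],
}


@dataclass(frozen=True)
class AdjustedCorrelation:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    adjusters: tuple[str, ...]


@dataclass(frozen=True)
class InteractionTest:
    modifier: str
    lrt_stat: float
    df: int
    p: float
    model_terms: tuple[str, ...]
    n: int


@dataclass(frozen=True)
class TermResult:
    """One candidate's final status in a stepwise model.

    For unselected terms, ``beta``/``se``/``p`` describe the coefficient the
    term would take if added to the final model — the number a dashed table
    cell reports a p-value for.
    """
    name: str
    selected: bool
    beta: float
    se: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    stratum: str
    outcome: str
    selected_terms: tuple[str, ...]
    terms: tuple[TermResult, ...]
    r2: float
    n: int
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _numeric_design(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Complete-case numeric copy of *cols*; sex encoded as sex_male 0/1."""
    out = pd.DataFrame(index=data.index)
    for c in cols:
        if c == "sex_male":
            out[c] = (data["sex"] == "M").astype(float)
        else:
            out[c] = pd.to_numeric(data[c], errors="coerce")
    return out.dropna()


def sex_difference_table(derived: pd.DataFrame,
                         continuous: list[str] | None = None,
                         categorical: list[str] | None = None) -> pd.DataFrame:
    """Descriptive table by sex with t-test / chi-square p-values.

    Continuous variables use the classical equal-variance Student t-test;
    categorical variables use an uncorrected chi-square test on the 2-way
    contingency table.
    """
    if continuous is None:
        continuous = ["age", "adiponectin", "pea", "bmi", "waist",
                      "triglycerides", "hdl", "glucose", "homa_ir", "sbp",
                      "dbp", "activity", "crp"]
    if categorical is None:
        categorical = ["diabetic", "alcohol", "education"]
    sex = derived["sex"]
    if sex.nunique() < 2:
        raise ValueError("both sexes must be present")
    rows = []
    for var in continuous:
        if var not in derived.columns:
            continue
        x = pd.to_numeric(derived.loc[sex == "F", var], errors="coerce").dropna()
        y = pd.to_numeric(derived.loc[sex == "M", var], errors="coerce").dropna()
        if len(x) < 2 or len(y) < 2:
            rows.append({"variable": var, "type": "continuous",
                         "testable": False})
            continue
        t, p = sps.ttest_ind(x, y, equal_var=True)
        rows.append({
            "variable": var, "type": "continuous", "testable": True,
            "mean_f": x.mean(), "sd_f": x.std(ddof=1),
            "mean_m": y.mean(), "sd_m": y.std(ddof=1),
            "stat": t, "p": p, "n": len(x) + len(y),
        })
    for var in categorical:
        if var not in derived.columns:
            continue
        sub = derived[[var, "sex"]].dropna()
        tab = pd.crosstab(sub["sex"], sub[var])
        if tab.shape != (2, 2) or (tab.values < 1).any():
            rows.append({"variable": var, "type": "categorical",
                         "testable": False})
            continue
        chi2, p, _, _ = sps.chi2_contingency(tab.values, correction=False)
        pct = sub.groupby("sex")[var].mean() * 100
        rows.append({
            "variable": var, "type": "categorical", "testable": True,
            "pct_f": pct.get("F", np.nan), "pct_m": pct.get("M", np.nan),
            "stat": chi2, "p": p, "n": len(sub),
        })
    return pd.DataFrame(rows)


def adjusted_pearson(x: str, y: str, data: pd.DataFrame,
                     adjusters: tuple[str, ...] = ("age", "sex_male"),
                     ) -> AdjustedCorrelation:
    """Pearson correlation of *x* and *y* after OLS removal of adjusters.

    Both variables are residualised on an intercept plus the adjusters; the
    p-value uses t = r * sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k degrees
    of freedom, k the number of adjusters.
    """
    cols = [x, y, *adjusters]
    df = _numeric_design(data, cols)
    k = len(adjusters)
    n = len(df)
    if n <= k + 2:
        raise ValueError(f"need more than {k + 2} complete cases; have {n}")
    Z = np.column_stack([np.ones(n), df[list(adjusters)].to_numpy()]) \
        if k else np.ones((n, 1))
    rx = df[x].to_numpy() - Z @ np.linalg.lstsq(Z, df[x].to_numpy(), rcond=None)[0]
    ry = df[y].to_numpy() - Z @ np.linalg.lstsq(Z, df[y].to_numpy(), rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        return AdjustedCorrelation(x, y, np.nan, np.nan, n, tuple(adjusters))
    r = float(np.corrcoef(rx, ry)[0, 1])
    dfree = n - 2 - k
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt(dfree / (1 - r_**2))
    p = float(2 * sps.t.sf(abs(t), dfree))
    return AdjustedCorrelation(x, y, r, p, n, tuple(adjusters))


def correlation_table(data: pd.DataFrame, focal: tuple[str, str],
                      covariates: list[str],
                      adjusters: tuple[str, ...] = ("age", "sex_male"),
                      ) -> pd.DataFrame:
    """Adjusted correlations of each focal variable with every covariate."""
    rows = []
    pairs = [(focal[0], focal[1])] + \
        [(f, c) for f in focal for c in covariates if c != f]
    for a, b in pairs:
        try:
            res = adjusted_pearson(a, b, data, adjusters)
            rows.append({"var_x": a, "var_y": b, "r": res.r, "p": res.p,
                         "n": res.n})
        except ValueError:
            rows.append({"var_x": a, "var_y": b, "r": np.nan, "p": np.nan,
                         "n": 0})
    return pd.DataFrame(rows)


def interaction_lrt(outcome: str, exposure: str, modifier: str,
                    covariates: list[str], data: pd.DataFrame,
                    ) -> InteractionTest:
    """Likelihood-ratio test of exposure-by-modifier effect modification.

    Fits nested Gaussian linear models (maximum likelihood) with and
    without the exposure x modifier product term; the statistic 2 * delta
    log-likelihood is referred to chi-square with one degree of freedom per
    interaction term.
    """
    cols = [outcome, exposure, modifier] + list(covariates)
    df = _numeric_design(data, cols)
    if df[modifier].nunique() <= 1:
        raise ValueError(f"modifier {modifier!r} is constant")
    y = df[outcome].to_numpy()
    base_terms = [exposure, modifier] + [c for c in covariates
                                         if c not in (exposure, modifier)]
    X0 = sm.add_constant(df[base_terms].to_numpy())
    inter = (df[exposure] * df[modifier]).to_numpy()[:, None]
    if np.ptp(inter) <= 1e-12 * max(1.0, float(np.abs(inter).max())):
        # constant product column: the nested models are identical
        return InteractionTest(modifier, 0.0, 1, 1.0, tuple(base_terms),
                               len(df))
    X1 = np.column_stack([X0, inter])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError(
            f"rank-deficient design: {exposure} x {modifier} interaction is "
            "collinear with the main-effect terms"
        )
    ll0 = sm.OLS(y, X0).fit().llf
    ll1 = sm.OLS(y, X1).fit().llf
    stat = max(2.0 * (ll1 - ll0), 0.0)  # clip numerical noise
    p = float(sps.chi2.sf(stat, 1))
    return InteractionTest(modifier, float(stat), 1, p,
                           tuple(base_terms), len(df))


def _ols_stats(X: np.ndarray, y: np.ndarray):
    """Coefficients, their SEs, RSS for least squares with design X."""
    n, p = X.shape
    beta, rss_arr, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - rank
    sigma2 = rss / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    return beta, se, rss, dof


def stepwise_forward(outcome: str, data: pd.DataFrame,
                     candidates: list[str], forced: tuple[str, ...] = (),
                     focus: str | None = None, alpha_enter: float = 0.05,
                     stratum: str = "all") -> RegressionResult:
    """Forward stepwise linear regression with a focal reported term.

    Starting from intercept + *forced* terms, repeatedly adds the candidate
    with the smallest partial-F p-value while that p-value is <= alpha_enter
    (no removal step).  Ties break by candidate-list order.  The *focus*
    term is an ordinary candidate but is always present in the report: if
    unselected, its would-be coefficient and p-value on entry into the
    final model are reported.
    """
    if focus is not None and focus not in candidates:
        candidates = [focus] + list(candidates)
    cols = [outcome, *forced, *candidates]
    df = _numeric_design(data, cols)
    n = len(df)
    warnings_: list[str] = []
    y = df[outcome].to_numpy()

    def design(terms):
        return np.column_stack([np.ones(n)] + [df[t].to_numpy() for t in terms])

    selected: list[str] = list(forced)
    remaining = [c for c in candidates if c not in selected]
    while remaining:
        if n <= len(selected) + 3:
            warnings_.append("too few observations to continue selection")
            break
        X_cur = design(selected)
        _, _, rss_cur, _ = _ols_stats(X_cur, y)
        best = None
        for cand in remaining:
            Xc = np.column_stack([X_cur, df[cand].to_numpy()])
            _, _, rss_c, dof_c = _ols_stats(Xc, y)
            if dof_c <= 0 or rss_c <= 0:
                continue
            f = (rss_cur - rss_c) / (rss_c / dof_c)
            p = float(sps.f.sf(max(f, 0.0), 1, dof_c))
            if best is None or p < best[1]:  # strict: first-listed wins ties
                best = (cand, p)
        if best is None or best[1] > alpha_enter:
            break
        selected.append(best[0])
        remaining.remove(best[0])

    X_fin = design(selected)
    beta, se, rss_fin, dof_fin = _ols_stats(X_fin, y)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss_fin / tss if tss > 0 else np.nan
    term_results = []
    for i, t in enumerate(selected, start=1):
        tt = beta[i] / se[i] if se[i] > 0 else np.nan
        p = float(2 * sps.t.sf(abs(tt), dof_fin)) if np.isfinite(tt) else np.nan
        term_results.append(TermResult(t, True, float(beta[i]), float(se[i]), p))
    for t in candidates:
        if t in selected:
            continue
        Xc = np.column_stack([X_fin, df[t].to_numpy()])
        b_c, se_c, _, dof_c = _ols_stats(Xc, y)
        tt = b_c[-1] / se_c[-1] if se_c[-1] > 0 else np.nan
        p = float(2 * sps.t.sf(abs(tt), dof_c)) if np.isfinite(tt) else np.nan
        term_results.append(TermResult(t, False, float(b_c[-1]),
                                       float(se_c[-1]), p))
    return RegressionResult(stratum, outcome, tuple(s for s in selected),
                            tuple(term_results), float(r2), n,
                            tuple(warnings_))


def stratified_analysis(derived: pd.DataFrame,
                        strata: tuple[str, ...] = ("obesity", "ir"),
                        outcome: str = "log_adiponectin",
                        exposure: str = "pea",
                        candidates: dict[str, list[str]] | None = None,
                        alpha_enter: float = 0.05,
                        min_n: int = 50,
                        sensitivity_no_diabetes: bool = True,
                        ) -> list[RegressionResult]:
    """Stepwise models of the outcome on the exposure within strata.

    ``obesity`` splits on the BMI >= 30 flag; ``ir`` splits on the
    upper-quartile HOMA-IR flag, with unmeasured HOMA-IR counted in the
    insulin-sensitive stratum (matching how the strata are sized in
    practice).  An optional sensitivity model restricts to participants
    without diabetes.  Strata below *min_n* are skipped.
    """
    candidates = candidates or DEFAULT_CANDIDATES
    masks: list[tuple[str, pd.Series, str]] = []
    if "obesity" in strata:
        masks += [("non-obese", derived["obese"] == 0, "obesity"),
                  ("obese", derived["obese"] == 1, "obesity")]
    if "ir" in strata:
        masks += [("non-IR", derived["insulin_resistant"] != 1, "ir"),
                  ("IR", derived["insulin_resistant"] == 1, "ir")]
    if sensitivity_no_diabetes:
        masks += [("no-diabetes", derived["diabetic"] == 0, "obesity")]
    results = []
    for label, mask, cand_key in masks:
        sub = derived[mask.fillna(False)]
        if len(sub) < min_n:
            continue
        res = stepwise_forward(outcome, sub, list(candidates[cand_key]),
                               focus=exposure, alpha_enter=alpha_enter,
                               stratum=label)
        results.append(res)
    return results


def results_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    """Flatten stepwise results into a long table (dash convention kept)."""
    rows = []
    for res in results:
        for t in res.terms:
            rows.append({
                "stratum": res.stratum, "term": t.name,
                "selected": t.selected,
                "beta": t.beta if t.selected else np.nan,
                "se": t.se if t.selected else np.nan,
                "beta_if_added": np.nan if t.selected else t.beta,
                "se_if_added": np.nan if t.selected else t.se,
                "p": t.p, "r2": res.r2, "n": res.n,
            })
    return pd.DataFrame(rows)
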