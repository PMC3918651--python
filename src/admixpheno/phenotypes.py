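"""Derived cardio-metabolic variables and classifications.

Implements the study definitions used downstream: BMI (kg/m^2), obesity
(BMI >= 30), HOMA-IR (fasting insulin [uU/mL] x fasting glucose [mmol/L]
/ 22.5), insulin resistance (upper quartile of the HOMA-IR distribution),
diabetes (fasting glucose >= 7.0 mmol/L or glucose-lowering medication),
and the natural-log transform of adiponectin.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MGDL_PER_MMOL",
    "compute_bmi",
    "classify_obesity",
    "compute_homa_ir",
    "classify_insulin_resistance",
    "classify_diabetes",
    "derive",
]

log = logging.getLogger(__name__)

#: molar mass conversion for glucose, mg/dL per mmol/L
MGDL_PER_MMOL = 18.016

#: columns expected in a raw cohort table (missing values allowed where noted)
COHORT_COLUMNS = [
    "individual_id", "age", "sex", "adiponectin", "weight", "height",
    "waist", "triglycerides", "hdl", "glucose", "insulin", "sbp", "dbp",
    "activity", "alcohol", "crp", "education", "diabetes_meds",
]


def compute_bmi(weight, height):
    """Body mass index: weight in kg divided by height in metres squared."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight[~np.isnan(weight)] <= 0) or np.any(height[~np.isnan(height)] <= 0):
        raise ValueError("weight and height must be positive")
    return weight / height**2


def classify_obesity(bmi):
    """Obesity flag: BMI >= 30 kg/m^2 (inclusive boundary); NaN propagates."""
    bmi = np.asarray(bmi, dtype=float)
    out = np.where(np.isnan(bmi), np.nan, (bmi >= 30.0).astype(float))
    return out


def compute_homa_ir(glucose, insulin, glucose_units: str = "mmol/L"):
    """HOMA-IR = fasting insulin (uU/mL) x fasting glucose (mmol/L) / 22.5.

    Glucose supplied in mg/dL (declared via *glucose_units*) is converted by
    dividing by 18.016 first.  Missing insulin yields missing HOMA-IR.
    """
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if glucose_units == "mg/dL":
        glucose = glucose / MGDL_PER_MMOL
    elif glucose_units != "mmol/L":
        raise ValueError(f"unknown glucose units {glucose_units!r}")
    with np.errstate(invalid="ignore"):
        if np.any(glucose <= 0) or np.any(insulin <= 0):
            raise ValueError("glucose and insulin must be positive where present")
    return insulin * glucose / 22.5


def classify_insulin_resistance(homa: np.ndarray):
    """Flag the upper quartile of the HOMA-IR distribution.

    Among the n non-missing values, individuals whose average rank exceeds
    0.75*n are flagged — the top 25% by rank, with ties sharing the flag of
    their rank block.  With 1190 distinct values this flags exactly 298.
    Missing HOMA-IR yields a missing flag.
    """
    homa = np.asarray(homa, dtype=float)
    obs = ~np.isnan(homa)
    n = int(obs.sum())
    if n < 4:
        raise ValueError("need at least 4 non-missing HOMA-IR values")
    ranks = rankdata(homa[obs], method="average")
    flagged = ranks > 0.75 * n
    if not flagged.any():
        warnings.warn("degenerate HOMA-IR distribution: no upper quartile",
                      stacklevel=2)
    out = np.full(homa.shape, np.nan)
    out[obs] = flagged.astype(float)
    return out


def classify_diabetes(glucose_mmol, meds):
    """Diabetes: fasting glucose >= 7.0 mmol/L or glucose-lowering treatment.

    Both inputs missing -> missing flag; a single present input decides if
    it is affirmative, otherwise the flag follows the available evidence.
    """
    glucose = np.atleast_1d(np.asarray(glucose_mmol, dtype=float))
    meds = np.atleast_1d(np.asarray(meds, dtype=float))
    flag = ((glucose >= 7.0) | (meds == 1)).astype(float)
    flag[np.isnan(glucose) & np.isnan(meds)] = np.nan
    return flag if flag.size > 1 else flag[0]


def derive(
    cohort: pd.DataFrame,
    pea: pd.DataFrame | None = None,
    glucose_units: str = "mmol/L",
) -> pd.DataFrame:
    """Join ancestry estimates to phenotypes and compute all derived columns.

    Parameters
    ----------
    cohort
        Raw phenotype table with the documented column roster.
    pea
        Optional frame with ``individual_id`` and ``s_hat`` (the estimated
        European ancestry proportion); inner-joined on id, with dropped ids
        logged.  When None the cohort must already carry a ``pea`` column.
    glucose_units
        Declared units of the ``glucose`` column; no autodetection.

    Returns
    -------
    DataFrame with the raw columns plus ``pea``, ``log_adiponectin``,
    ``bmi``, ``homa_ir``, ``obese``, ``insulin_resistant``, ``diabetic``.
    """
    df = cohort.copy()
    if df["individual_id"].duplicated().any():
        raise ValueError("duplicate individual ids in cohort table")
    if pea is not None:
        before = len(df)
        merged = df.merge(
            pea[["individual_id", "s_hat"]].rename(columns={"s_hat": "pea"}),
            on="individual_id", how="inner",
        )
        if len(merged) == 0:
            raise ValueError("no overlap between phenotype ids and ancestry ids")
        if len(merged) < before:
            log.info("derive: dropped %d individuals without ancestry estimate",
                     before - len(merged))
        df = merged
    elif "pea" not in df.columns:
        raise ValueError("cohort has no 'pea' column and no estimates supplied")

    adipo = df["adiponectin"].to_numpy(dtype=float)
    if np.any(adipo[~np.isnan(adipo)] <= 0):
        raise ValueError("adiponectin must be positive where present")
    df["log_adiponectin"] = np.log(adipo)
    df["bmi"] = compute_bmi(df["weight"], df["height"])
    df["obese"] = classify_obesity(df["bmi"])
    glucose_mmol = df["glucose"].to_numpy(dtype=float)
    if glucose_units == "mg/dL":
        glucose_mmol = glucose_mmol / MGDL_PER_MMOL
    df["homa_ir"] = compute_homa_ir(glucose_mmol, df["insulin"])
    try:
        df["insulin_resistant"] = classify_insulin_resistance(df["homa_ir"].to_numpy())
    except ValueError:
        # quartile undefined on tiny tables; leave the flag missing
        warnings.warn("too few HOMA-IR values to define the upper quartile",
                      stacklevel=2)
        df["insulin_resistant"] = np.nan
    df["diabetic"] = classify_diabetes(glucose_mmol, df["diabetes_meds"])

    n_missing = df.isna().sum()
    for col, cnt in n_missing.items():
        if cnt:
            log.info("derive: %s has %d missing of %d", col, cnt, len(df))
    return df


def missingness_report(derived: pd.DataFrame) -> pd.DataFrame:
    """Per-variable count of non-missing values (mirrors per-variable n)."""
    return pd.DataFrame({
        "variable": derived.columns,
        "n_nonmissing": [derived[c].notna().sum() for c in derived.columns],
    })
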