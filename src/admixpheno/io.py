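"""Readers and writers for the pipeline's plain-text interchange formats.

All data move as TSV/CSV with documented headers:

* frequency table: TSV ``marker_id  counted_allele  p_afr  p_eur``;
* genotype matrix: TSV, first column ``individual_id``, remaining columns
  marker ids, entries 0/1/2/NA (a PLINK-additive-export-like layout);
* phenotype table and derived table: CSV with the documented roster;
* ancestry estimates: CSV ``individual_id,s_hat,se,loglik,n_used,flags``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestry import (
    MISSING,
    AIMPanel,
    GenotypeMatrix,
    PanelValidationError,
    clamp_frequencies,
)

log = logging.getLogger(__name__)

FREQ_COLUMNS = ["marker_id", "counted_allele", "p_afr", "p_eur"]


def read_frequency_table(path, eps: float = 0.001) -> AIMPanel:
    """Read and validate an ancestral allele-frequency table (TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    if list(df.columns) != FREQ_COLUMNS:
        raise PanelValidationError(
            f"{path}: expected header {FREQ_COLUMNS}, got {list(df.columns)}"
        )
    for col in ("p_afr", "p_eur"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals > 1)]
        if len(bad):
            i = bad[0]
            raise PanelValidationError(
                f"{path} line {i + 2}: {col}={df.loc[i, col]!r} invalid for "
                f"marker {df.loc[i, 'marker_id']}"
            )
        df[col] = vals
    panel = AIMPanel(
        df["marker_id"].to_numpy(dtype=object),
        df["counted_allele"].to_numpy(dtype=object),
        df["p_afr"].to_numpy(),
        df["p_eur"].to_numpy(),
        eps=eps,
    )
    return clamp_frequencies(panel)


def write_frequency_table(panel: AIMPanel, path) -> None:
    pd.DataFrame({
        "marker_id": panel.marker_id,
        "counted_allele": panel.counted_allele,
        "p_afr": panel.p_afr,
        "p_eur": panel.p_eur,
    }).to_csv(path, sep="\t", index=False)


def read_genotypes(path, panel: AIMPanel) -> GenotypeMatrix:
    """Read a genotype dosage TSV and align it to *panel* marker order.

    Columns not in the panel are dropped with a warning; entries must be
    0, 1, 2 or NA.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if df.columns[0] != "individual_id":
        raise PanelValidationError(f"{path}: first column must be individual_id")
    known = set(panel.marker_id)
    unknown = [c for c in df.columns[1:] if c not in known]
    if unknown:
        log.warning("%s: dropping %d unknown marker column(s): %s ...",
                    path, len(unknown), unknown[:3])
        df = df.drop(columns=unknown)
    marker_cols = [m for m in panel.marker_id if m in df.columns]
    if not marker_cols:
        raise PanelValidationError(f"{path}: no panel markers present")
    dose = df[marker_cols].to_numpy(dtype=float)
    valid = np.isnan(dose) | np.isin(dose, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise PanelValidationError(
            f"{path}: dosage {dose[i, j]!r} for {df.iloc[i, 0]} at "
            f"{marker_cols[j]} not in 0/1/2/NA"
        )
    sub = AIMPanel(
        np.asarray(marker_cols, dtype=object),
        panel.counted_allele[np.isin(panel.marker_id, marker_cols)],
        panel.p_afr[np.isin(panel.marker_id, marker_cols)],
        panel.p_eur[np.isin(panel.marker_id, marker_cols)],
        eps=panel.eps,
    )
    gm = GenotypeMatrix(df["individual_id"].to_numpy(dtype=object), dose,
                        np.asarray(marker_cols, dtype=object))
    return gm.align_to(sub)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    dose = gm.dosage.astype(object)
    dose[gm.dosage == MISSING] = "NA"
    df = pd.DataFrame(dose, columns=list(gm.marker_id))
    df.insert(0, "individual_id", gm.individual_id)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs an individual_id column")
    return df
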