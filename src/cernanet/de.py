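"""Differential-expression screening between case and control groups.

The test is a deliberately simple surrogate for a full negative-binomial
count model: counts are library-size normalised to counts-per-million
(CPM), log2-transformed with a pseudocount of 1, and compared per gene
with a two-sided Welch t-test. P-values are Benjamini-Hochberg adjusted
*within each RNA class*, because the three RNA classes come from separate
experiments and are screened separately. An import path exists for
externally computed DE tables (e.g. real edgeR output), so the surrogate
only ever has to be adequate on synthetic data.

Fold change is oriented case over control: ``log2fc > 0`` means higher in
the case (disease) group.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import read_de_table
from .types import DE_COLUMNS, ExpressionMatrix, ValidationError, validate_de_table

logger = logging.getLogger(__name__)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million library-size normalisation (per sample column)."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValidationError("sample with zero library size")
    return counts.div(libsize, axis=1) * 1e6


def test_differential(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene case-vs-control test on log2(CPM + 1).

    Returns a DE table with columns gene, rna_class, log2fc, pvalue,
    adj_pvalue, direction. Genes with zero variance in both groups and
    equal means get p = 1.
    """
    case = matrix.samples_of_group("case")
    control = matrix.samples_of_group("control")
    if len(case) < 2 or len(control) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got case={len(case)}, control={len(control)}"
        )
    log_expr = np.log2(cpm(matrix.counts) + 1.0)
    x = log_expr[case].to_numpy()
    y = log_expr[control].to_numpy()

    mean_case_cpm = (2.0 ** x - 1.0).mean(axis=1)
    mean_ctrl_cpm = (2.0 ** y - 1.0).mean(axis=1)
    log2fc = np.log2(mean_case_cpm + 1.0) - np.log2(mean_ctrl_cpm + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    pvalue = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: identical values -> no evidence
    pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)

    table = pd.DataFrame({
        "gene": matrix.gene_ids,
        "rna_class": matrix.rna_class.to_numpy(),
        "log2fc": log2fc,
        "pvalue": pvalue,
    })
    table = adjust_within_class(table)
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    return validate_de_table(table.reset_index(drop=True))


def adjust_within_class(table: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment applied separately per RNA class."""
    table = table.copy()
    table["adj_pvalue"] = np.nan
    for _cls, idx in table.groupby("rna_class").groups.items():
        table.loc[idx, "adj_pvalue"] = multipletests(
            table.loc[idx, "pvalue"].to_numpy(), method="fdr_bh"
        )[1]
    return table


def screen(table: pd.DataFrame, lfc_threshold: float = 1.0,
           adjp_threshold: float = 0.05) -> pd.DataFrame:
    """Retain genes with |log2fc| > lfc AND adj_p < alpha (both strict).

    Idempotent; tightening either threshold never adds records.
    """
    keep = (table["log2fc"].abs() > lfc_threshold) & (table["adj_pvalue"] < adjp_threshold)
    return table[keep].reset_index(drop=True)


def summarize_directions(table: pd.DataFrame,
                         classes: Sequence[str] = ("mRNA", "lncRNA", "miRNA")) -> pd.DataFrame:
    """Per-class up/down composition of a (screened) DE table.

    ``pct_up`` is 100 * n_up / n_total rounded to two decimals, NaN for an
    empty class.
    """
    rows = []
    for cls in classes:
        sub = table[table["rna_class"] == cls]
        n_total = len(sub)
        n_up = int((sub["direction"] == "up").sum())
        pct = round(100.0 * n_up / n_total, 2) if n_total else float("nan")
        rows.append({"rna_class": cls, "n_total": n_total, "n_up": n_up,
                     "n_down": n_total - n_up, "pct_up": pct})
    return pd.DataFrame(rows)


def merge_external_de(table: pd.DataFrame, paths: Sequence) -> pd.DataFrame:
    """Union the computed DE table with imported ones (e.g. literature lncRNAs).

    A gene present in both with *opposite* direction is a hard error; a
    duplicate with the same direction keeps the computed record.
    """
    merged = table.copy()
    for path in paths:
        ext = read_de_table(path)
        known = merged.set_index("gene")["direction"]
        overlap = ext[ext["gene"].isin(known.index)]
        conflicts = overlap[overlap["direction"].to_numpy()
                            != known.loc[overlap["gene"]].to_numpy()]
        if len(conflicts):
            raise ValidationError(
                "conflicting DE direction for genes: "
                + ", ".join(sorted(conflicts["gene"]))
            )
        new = ext[~ext["gene"].isin(known.index)]
        if len(overlap):
            logger.info("import %s: %d genes already present, kept computed records",
                        path, len(overlap))
        merged = pd.concat([merged, new[DE_COLUMNS]], ignore_index=True)
    return validate_de_table(merged)
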