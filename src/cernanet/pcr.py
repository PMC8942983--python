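"""Relative quantification arithmetic for qRT-PCR validation (2^-ddCt).

A Ct table holds threshold-cycle values for a target gene and a reference
gene (e.g. beta-actin) across case and control samples, with replicates.
Replicates are averaged at the Ct level, then:

    dCt  = mean Ct(target) - mean Ct(reference)        per sample
    ddCt = dCt(sample)     - mean dCt(control group)
    fold = 2 ** (-ddCt)

Group comparison uses the two-sided equal-variance Student t-test (with a
Welch option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError

CT_COLUMNS = ["sample", "condition", "gene", "ct", "replicate"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive")
    bad = set(table["condition"].unique()) - {"case", "control"}
    if bad:
        raise ValidationError(f"condition must be case/control, got {sorted(bad)}")
    bad = set(table["gene"].unique()) - {"target", "reference"}
    if bad:
        raise ValidationError(f"gene must be target/reference, got {sorted(bad)}")
    for sample, sub in table.groupby("sample"):
        if "reference" not in set(sub["gene"]):
            raise ValidationError(f"sample {sample!r} has no reference-gene Ct")
        if "target" not in set(sub["gene"]):
            raise ValidationError(f"sample {sample!r} has no target-gene Ct")
    return table


def delta_delta_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample ddCt and 2^-ddCt fold change, normalised to the control mean.

    Returns (sample, condition, delta_ct, delta_delta_ct, fold_change),
    control samples included (their folds centre on 1 by construction).
    """
    validate_ct_table(table)
    mean_ct = table.groupby(["sample", "condition", "gene"])["ct"].mean().unstack("gene")
    dct = (mean_ct["target"] - mean_ct["reference"]).rename("delta_ct").reset_index()
    control_dct = dct.loc[dct["condition"] == "control", "delta_ct"]
    if control_dct.empty:
        raise ValidationError("no control samples to normalise against")
    dct["delta_delta_ct"] = dct["delta_ct"] - control_dct.mean()
    dct["fold_change"] = 2.0 ** (-dct["delta_delta_ct"])
    return dct[["sample", "condition", "delta_ct", "delta_delta_ct", "fold_change"]]


@dataclass
class GroupComparison:
    t_statistic: float
    pvalue: float
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float


def compare_groups(folds_case, folds_control, equal_var: bool = True) -> GroupComparison:
    """Two-sided t-test on fold changes; Student by default, Welch optional."""
    x = np.asarray(folds_case, dtype=float)
    y = np.asarray(folds_control, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("need >= 2 values per group for a t-test")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return GroupComparison(
        t_statistic=float(t), pvalue=float(p),
        mean_case=float(x.mean()), sd_case=float(x.std(ddof=1)),
        mean_control=float(y.mean()), sd_control=float(y.std(ddof=1)),
    )
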