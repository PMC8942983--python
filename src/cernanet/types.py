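"""Core in-memory containers shared across the pipeline.

Tabular data are plain :class:`pandas.DataFrame` objects with documented
column schemas (validated by the helpers here); the expression matrix is a
small dataclass bundling counts with gene- and sample-level annotations;
ceRNA networks are :class:`networkx.Graph` objects with typed nodes/edges.
Gene and sample identifiers are opaque, case-sensitive strings — no
symbol/alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")
GROUPS = ("case", "control")

#: column schema of a differential-expression table
DE_COLUMNS = ["gene", "rna_class", "log2fc", "pvalue", "adj_pvalue", "direction"]

#: column schema of a miRNA-target interaction table
INTERACTION_COLUMNS = ["mirna", "target", "target_class", "source_db", "score"]

#: column schema of a clinical survival table
CLINICAL_COLUMNS = ["sample", "time", "event"]


class ValidationError(ValueError):
    """Raised when an input container violates its schema invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x samples count matrix with RNA-class and group annotations.

    Parameters
    ----------
    counts
        Non-negative numeric matrix; index = gene ids, columns = sample ids.
    rna_class
        Per-gene label in {"lncRNA", "miRNA", "mRNA"}, indexed like
        ``counts.index``.
    group
        Per-sample label in {"case", "control"}, indexed like
        ``counts.columns``.
    """

    counts: pd.DataFrame
    rna_class: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.counts.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        cols = self.counts.columns
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        if not idx.equals(self.rna_class.index):
            raise ValidationError("rna_class index must match counts.index")
        bad = set(self.rna_class.unique()) - set(RNA_CLASSES)
        if bad:
            raise ValidationError(f"unknown RNA class labels: {sorted(bad)}")
        if not cols.equals(self.group.index):
            raise ValidationError("group index must match counts.columns")
        bad = set(self.group.unique()) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def genes_of_class(self, rna_class: str) -> pd.Index:
        return self.counts.index[self.rna_class == rna_class]

    def samples_of_group(self, group: str) -> pd.Index:
        return self.counts.columns[self.group == group]


def validate_interactions(table: pd.DataFrame, score_bearing: Iterable[str] = ()) -> pd.DataFrame:
    """Check an interaction table against its schema and return it.

    ``score_bearing`` names the source databases whose records must carry a
    score (e.g. a TargetScan-style export).
    """
    missing = [c for c in INTERACTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"interaction table missing columns: {missing}")
    dup = table.duplicated(subset=["mirna", "target", "source_db"])
    if dup.any():
        row = table[dup].iloc[0]
        raise ValidationError(
            f"duplicate interaction record: ({row['mirna']}, {row['target']}, {row['source_db']})"
        )
    bad = set(table["target_class"].unique()) - {"lncRNA", "mRNA"}
    if bad:
        raise ValidationError(f"interaction target_class must be lncRNA or mRNA, got {sorted(bad)}")
    for db in score_bearing:
        sub = table[table["source_db"] == db]
        if sub["score"].isna().any():
            mi = sub[sub["score"].isna()].iloc[0]["mirna"]
            raise ValidationError(f"missing score on record from score-bearing db {db!r} (miRNA {mi!r})")
    return table


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    if table["sample"].duplicated().any():
        dup = table.loc[table["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"duplicate sample id: {dup!r}")
    if (table["time"] <= 0).any():
        raise ValidationError("survival times must be > 0")
    if not set(table["event"].unique()) <= {0, 1}:
        raise ValidationError("event must be 0 (censored) or 1 (death)")
    return table


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"DE table missing columns: {missing}")
    if table["gene"].duplicated().any():
        dup = table.loc[table["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"duplicate gene in DE table: {dup!r}")
    mism = table[(table["log2fc"] > 0) != (table["direction"] == "up")]
    if len(mism):
        raise ValidationError(
            f"direction inconsistent with log2fc sign for gene {mism.iloc[0]['gene']!r}"
        )
    return table


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line)."""

    set_id: str
    description: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id!r} is empty")


@dataclass
class GeneSetCollection:
    """Mapping of set id -> :class:`GeneSet`, e.g. a pathway collection."""

    sets: dict = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.set_id in self.sets:
            raise ValidationError(f"duplicate set id: {gene_set.set_id!r}")
        self.sets[gene_set.set_id] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets
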