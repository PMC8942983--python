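"""Consensus filtering of multi-database miRNA target predictions.

miRNA->mRNA predictions from several databases are reduced to a consensus
edge set: a pair counts only if it appears in at least ``min_db`` distinct
databases. A score-bearing (TargetScan-style) table is filtered first by
its context score, so a sub-threshold record never counts as support.
miRNA->lncRNA predictions come from a single (starBase-style) source and
are passed through with deduplication only — there is no consensus rule on
the lncRNA side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .types import ValidationError


@dataclass
class ConsensusEdgeSet:
    """Consensus miRNA target edges feeding triplet assembly.

    ``mirna_mrna``: mapping (mirna, mrna) -> sorted tuple of supporting
    database names. ``mirna_lnc``: set of (mirna, lncrna) pairs.
    """

    mirna_mrna: dict = field(default_factory=dict)
    mirna_lnc: set = field(default_factory=set)


def filter_targetscan(table: pd.DataFrame, score_threshold: float = -0.1) -> pd.DataFrame:
    """Keep records with context score strictly below ``score_threshold``.

    Every record must carry a score; a missing one is a hard error because
    it cannot be compared against the threshold.
    """
    if table.empty:
        return table
    if table["score"].isna().any():
        row = table[table["score"].isna()].iloc[0]
        raise ValidationError(
            f"missing score on record ({row['mirna']}, {row['target']}) "
            f"from score-bearing db {row['source_db']!r}"
        )
    return table[table["score"] < score_threshold].reset_index(drop=True)


def consensus_mrna_targets(table: pd.DataFrame, min_db: int = 2) -> dict:
    """(miRNA, mRNA) pairs supported by >= ``min_db`` distinct databases.

    ``table`` is the merged interaction table with the score-bearing rows
    already filtered. Returns a mapping pair -> sorted supporting-db tuple.
    """
    mrna = table[table["target_class"] == "mRNA"]
    support = (
        mrna.groupby(["mirna", "target"])["source_db"]
        .agg(lambda s: tuple(sorted(set(s))))
    )
    return {
        pair: dbs for pair, dbs in support.items() if len(dbs) >= min_db
    }


def lncrna_targets(table: pd.DataFrame) -> set:
    """Deduplicated (miRNA, lncRNA) pairs from the single lncRNA-target source."""
    lnc = table[table["target_class"] == "lncRNA"]
    return set(zip(lnc["mirna"], lnc["target"]))


def build_consensus(mrna_table: pd.DataFrame, lnc_table: pd.DataFrame,
                    score_db: str | None = "TargetScan",
                    score_threshold: float = -0.1,
                    min_db: int = 2) -> ConsensusEdgeSet:
    """One-call consensus: score-filter, then the >= min_db rule, then lncRNA pass-through."""
    if score_db is not None and not mrna_table.empty:
        scored = mrna_table[mrna_table["source_db"] == score_db]
        rest = mrna_table[mrna_table["source_db"] != score_db]
        mrna_table = pd.concat(
            [rest, filter_targetscan(scored, score_threshold)], ignore_index=True
        )
    return ConsensusEdgeSet(
        mirna_mrna=consensus_mrna_targets(mrna_table, min_db=min_db),
        mirna_lnc=lncrna_targets(lnc_table),
    )
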