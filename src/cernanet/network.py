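"""Competing-triplet assembly and tripartite ceRNA network construction.

A competing triplet (lncRNA, miRNA, mRNA) requires that the miRNA targets
both the lncRNA and the mRNA, all three pass the differential-expression
screen, and the lncRNA and mRNA share a DE direction opposite to the
miRNA's. "Negatively co-expressed" is operationalised as opposite DE
direction rather than a sample-level correlation coefficient — the three
RNA classes typically come from different cohorts, so cross-sample
correlation is not generally computable; an optional correlation filter is
available for same-cohort data.

Triplets are partitioned by the lncRNA's direction into an
"lncRNA-upregulated" and an "lncRNA-downregulated" group, and each group's
triplets are unioned into one tripartite network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .de import cpm
from .targets import ConsensusEdgeSet
from .types import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

GROUP_LNC_UP = "lnc_up"
GROUP_LNC_DOWN = "lnc_down"


@dataclass(frozen=True, order=True)
class CompetingTriplet:
    lncrna: str
    mirna: str
    mrna: str
    group: str  # lnc_up | lnc_down


def _direction_map(de_table: pd.DataFrame) -> dict:
    return dict(zip(de_table["gene"], de_table["direction"]))


def build_pairs(de_table: pd.DataFrame, edges: ConsensusEdgeSet,
                expression: ExpressionMatrix | None = None,
                min_neg_corr: float = 0.0) -> tuple:
    """Direction-opposed (lncRNA, miRNA) and (miRNA, mRNA) pairs.

    An edge survives only if both endpoints are in the DE table and their
    directions are opposite; edges touching unknown genes are dropped with
    a logged count. With ``expression`` given, pairs additionally need a
    Pearson correlation < -``min_neg_corr`` on log2(CPM+1) across samples.

    Returns ``(lnc_mi_pairs, mi_mrna_pairs)`` as sets of id pairs with the
    miRNA first in the mRNA pairs and last in the lncRNA pairs dropped —
    concretely: {(lncrna, mirna)}, {(mirna, mrna)}.
    """
    direction = _direction_map(de_table)
    corr = _negative_correlation_test(expression, min_neg_corr) if expression is not None else None

    lnc_mi = set()
    dropped_unknown = 0
    for mirna, lnc in edges.mirna_lnc:
        if mirna not in direction or lnc not in direction:
            dropped_unknown += 1
            continue
        if direction[mirna] != direction[lnc] and (corr is None or corr(mirna, lnc)):
            lnc_mi.add((lnc, mirna))

    mi_mrna = set()
    for (mirna, mrna), _dbs in edges.mirna_mrna.items():
        if mirna not in direction or mrna not in direction:
            dropped_unknown += 1
            continue
        if direction[mirna] != direction[mrna] and (corr is None or corr(mirna, mrna)):
            mi_mrna.add((mirna, mrna))

    if dropped_unknown:
        logger.info("build_pairs: %d edges dropped (endpoint not in DE table)",
                    dropped_unknown)
    return lnc_mi, mi_mrna


def _negative_correlation_test(expression: ExpressionMatrix, min_neg_corr: float):
    log_expr = np.log2(cpm(expression.counts) + 1.0)

    def negatively_correlated(a: str, b: str) -> bool:
        if a not in log_expr.index or b not in log_expr.index:
            return False
        x, y = log_expr.loc[a], log_expr.loc[b]
        if x.std() == 0 or y.std() == 0:
            return False
        return float(np.corrcoef(x, y)[0, 1]) < -min_neg_corr

    return negatively_correlated


def assemble_triplets(lnc_mi_pairs: Iterable, mi_mrna_pairs: Iterable,
                      de_table: pd.DataFrame) -> list:
    """Join the two pair sets on the shared miRNA into competing triplets.

    Output is deterministically sorted by (lncrna, mirna, mrna). The group
    label follows the lncRNA's DE direction.
    """
    direction = _direction_map(de_table)
    by_mirna = {}
    for mirna, mrna in mi_mrna_pairs:
        by_mirna.setdefault(mirna, []).append(mrna)
    triplets = []
    for lnc, mirna in lnc_mi_pairs:
        for mrna in by_mirna.get(mirna, ()):
            group = GROUP_LNC_UP if direction[lnc] == "up" else GROUP_LNC_DOWN
            triplets.append(CompetingTriplet(lnc, mirna, mrna, group))
    return sorted(triplets)


def build_network(triplets: Sequence[CompetingTriplet],
                  de_table: pd.DataFrame | None = None) -> tuple:
    """Union each group's triplets into one tripartite network.

    Returns ``(lnc_up_network, lnc_down_network)`` as networkx graphs with
    node attributes ``rna_class``/``direction`` and edge attributes
    ``kind``/``triplets`` (the triplets inducing the edge). Edge
    multiplicity is collapsed.
    """
    direction = _direction_map(de_table) if de_table is not None else {}
    nets = {}
    for group in (GROUP_LNC_UP, GROUP_LNC_DOWN):
        g = nx.Graph(group=group)
        nets[group] = g
    for t in triplets:
        g = nets[t.group]
        g.add_node(t.lncrna, rna_class="lncRNA", direction=direction.get(t.lncrna, ""))
        g.add_node(t.mirna, rna_class="miRNA", direction=direction.get(t.mirna, ""))
        g.add_node(t.mrna, rna_class="mRNA", direction=direction.get(t.mrna, ""))
        for u, v, kind in ((t.lncrna, t.mirna, "lncRNA-miRNA"),
                           (t.mirna, t.mrna, "miRNA-mRNA")):
            if g.has_edge(u, v):
                g.edges[u, v]["triplets"].append(t)
            else:
                g.add_edge(u, v, kind=kind, triplets=[t])
    for g in nets.values():
        assert_tripartite(g)
    logger.info(
        "networks: lnc_up %d nodes / %d edges; lnc_down %d nodes / %d edges",
        nets[GROUP_LNC_UP].number_of_nodes(), nets[GROUP_LNC_UP].number_of_edges(),
        nets[GROUP_LNC_DOWN].number_of_nodes(), nets[GROUP_LNC_DOWN].number_of_edges(),
    )
    return nets[GROUP_LNC_UP], nets[GROUP_LNC_DOWN]


def assert_tripartite(network: nx.Graph) -> None:
    """Raise if any edge violates the lncRNA-miRNA / miRNA-mRNA structure."""
    for u, v in network.edges():
        classes = {network.nodes[u]["rna_class"], network.nodes[v]["rna_class"]}
        if classes not in ({"lncRNA", "miRNA"}, {"miRNA", "mRNA"}):
            raise ValidationError(f"non-tripartite edge {u!r}-{v!r}: {sorted(classes)}")


def network_summary(network: nx.Graph) -> dict:
    """Node counts per RNA class plus the edge count (the figure-legend tallies)."""
    counts = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
    for _, data in network.nodes(data=True):
        counts[data["rna_class"]] += 1
    counts["edges"] = network.number_of_edges()
    return counts


def triplets_to_frame(triplets: Sequence[CompetingTriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.lncrna, t.mirna, t.mrna, t.group) for t in triplets],
        columns=["lncRNA", "miRNA", "mRNA", "group"],
    )
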