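"""Topological ranking of lncRNAs in a tripartite ceRNA network.

For each lncRNA three quantities are counted: its node degree, its *first
relationship pairs* (distinct lncRNA-miRNA edges, equal to its degree in a
tripartite network) and its *secondary relationship pairs* (distinct
miRNA-mRNA edges whose miRNA neighbours it). Secondary pairs count edges,
not paths: an mRNA reachable through two different miRNAs contributes two
pairs. Key lncRNAs are the ones in the top-k of BOTH the degree ranking
and the total-pairs ranking. Hub nodes are those with degree strictly
exceeding a threshold (default 5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LncRNATopologyRecord:
    lncrna_id: str
    node_degree: int
    first_pairs: int
    secondary_pairs: int

    @property
    def total_pairs(self) -> int:
        return self.first_pairs + self.secondary_pairs


def node_degrees(network: nx.Graph) -> dict:
    """Degree (number of distinct incident edges) of every node."""
    return dict(network.degree())


def hub_nodes(network: nx.Graph, threshold: int = 5) -> pd.DataFrame:
    """Nodes with degree strictly greater than ``threshold``.

    Returns a frame (node, rna_class, degree) sorted by degree descending,
    id ascending; per-class counts are in ``hub_nodes(...).groupby``-land
    or via :func:`hub_class_counts`.
    """
    rows = [
        {"node": n, "rna_class": network.nodes[n].get("rna_class", ""), "degree": d}
        for n, d in network.degree()
        if d > threshold
    ]
    df = pd.DataFrame(rows, columns=["node", "rna_class", "degree"])
    return df.sort_values(["degree", "node"], ascending=[False, True]).reset_index(drop=True)


def hub_class_counts(hubs: pd.DataFrame) -> dict:
    return hubs.groupby("rna_class").size().to_dict()


def count_pairs(network: nx.Graph, lncrna_id: str) -> LncRNATopologyRecord:
    """First/secondary relationship pairs for one lncRNA node."""
    if lncrna_id not in network:
        raise ValidationError(f"unknown node: {lncrna_id!r}")
    if network.nodes[lncrna_id].get("rna_class") != "lncRNA":
        raise ValidationError(f"{lncrna_id!r} is not an lncRNA node")
    mirnas = [n for n in network.neighbors(lncrna_id)
              if network.nodes[n].get("rna_class") == "miRNA"]
    first = len(mirnas)
    secondary = sum(
        1
        for m in mirnas
        for n in network.neighbors(m)
        if network.nodes[n].get("rna_class") == "mRNA"
    )
    return LncRNATopologyRecord(
        lncrna_id=lncrna_id,
        node_degree=network.degree(lncrna_id),
        first_pairs=first,
        secondary_pairs=secondary,
    )


def rank_lncrnas(network: nx.Graph) -> pd.DataFrame:
    """Full topology table, sorted by (degree desc, total pairs desc, id asc).

    Columns mirror the published layout: rank number, gene name, node
    degree, lncRNA-miRNA pairs, miRNA-mRNA pairs, total.
    """
    lncs = [n for n, d in network.nodes(data=True) if d.get("rna_class") == "lncRNA"]
    records = [count_pairs(network, lnc) for lnc in lncs]
    df = pd.DataFrame({
        "gene": [r.lncrna_id for r in records],
        "node_degree": [r.node_degree for r in records],
        "lnc_mirna_pairs": [r.first_pairs for r in records],
        "mi_mrna_pairs": [r.secondary_pairs for r in records],
        "total_pairs": [r.total_pairs for r in records],
    })
    df = df.sort_values(
        ["node_degree", "total_pairs", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df.insert(0, "number", range(1, len(df) + 1))
    return df


def select_key_lncrnas(ranked: pd.DataFrame, k: int = 3) -> list:
    """LncRNAs in the top-k of both the degree and the total-pairs rankings.

    May return fewer than ``k`` ids; an empty intersection is reported with
    a warning. Output sorted like the main ranking.
    """
    by_degree = ranked.sort_values(["node_degree", "gene"], ascending=[False, True])
    by_total = ranked.sort_values(["total_pairs", "gene"], ascending=[False, True])
    top_degree = set(by_degree["gene"].head(k))
    top_total = set(by_total["gene"].head(k))
    keys = top_degree & top_total
    if not keys:
        logger.warning("select_key_lncrnas: degree and total-pairs top-%d sets are disjoint", k)
    return [g for g in ranked["gene"] if g in keys]


def extract_subnetwork(network: nx.Graph, lncrna_id: str) -> nx.Graph:
    """Sub-network of one lncRNA: its miRNA neighbours and their mRNA neighbours.

    The induced subgraph on {lncRNA} + miRNA neighbours + those miRNAs'
    mRNA neighbours, so it contains exactly the lncRNA-miRNA and
    miRNA-mRNA edges that the pair counts enumerate. Idempotent.
    """
    if lncrna_id not in network:
        raise ValidationError(f"unknown node: {lncrna_id!r}")
    if network.nodes[lncrna_id].get("rna_class") != "lncRNA":
        raise ValidationError(f"{lncrna_id!r} is not an lncRNA node")
    mirnas = {n for n in network.neighbors(lncrna_id)
              if network.nodes[n].get("rna_class") == "miRNA"}
    mrnas = {
        n
        for m in mirnas
        for n in network.neighbors(m)
        if network.nodes[n].get("rna_class") == "mRNA"
    }
    nodes = {lncrna_id} | mirnas | mrnas
    sub = network.subgraph(nodes).copy()
    sub.graph = dict(network.graph, subnetwork_of=lncrna_id)
    return sub


def first_mrna_neighbors(network: nx.Graph, lncrna_id: str) -> set:
    """The mRNAs in the lncRNA's sub-network (its enrichment query set)."""
    sub = extract_subnetwork(network, lncrna_id)
    return {n for n, d in sub.nodes(data=True) if d.get("rna_class") == "mRNA"}
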