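"""Readers and writers for the plain-text formats the pipeline touches.

TSV (tab-separated, UTF-8, header row) is the canonical tabular dialect.
Network exports target Cytoscape: SIF, GraphML and a flat edge TSV.
Readers never silently drop records — anything rejected is counted and
logged at WARNING level.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .types import (
    CLINICAL_COLUMNS,
    DE_COLUMNS,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ValidationError,
    validate_clinical,
    validate_de_table,
    validate_interactions,
)

logger = logging.getLogger(__name__)


def read_counts(path, class_map: Mapping[str, str] | None = None,
                group_map: Mapping[str, str] | None = None,
                drop_unknown_class: bool = False) -> ExpressionMatrix:
    """Read a counts TSV (first column gene ids, header row sample ids).

    ``class_map`` maps gene id -> RNA class and ``group_map`` maps sample
    id -> case/control; both may also be supplied as extra columns/rows in
    separate sidecar files by the caller. Genes with no class are a hard
    error unless ``drop_unknown_class`` is set, in which case they are
    dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id: {dup!r}")
    if class_map is None:
        raise ValidationError("class_map is required: per-gene RNA class labels")
    if group_map is None:
        raise ValidationError("group_map is required: per-sample case/control labels")
    unknown = [g for g in df.index if g not in class_map]
    if unknown:
        if not drop_unknown_class:
            raise ValidationError(f"genes with unknown RNA class: {unknown[:5]}")
        logger.warning("dropping %d genes with unknown RNA class", len(unknown))
        df = df.drop(index=unknown)
    rna_class = pd.Series({g: class_map[g] for g in df.index}).reindex(df.index)
    group = pd.Series({s: group_map[s] for s in df.columns}).reindex(df.columns)
    return ExpressionMatrix(counts=df, rna_class=rna_class, group=group)


def write_counts(matrix: ExpressionMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene")


def read_interactions(paths: Sequence, db_names: Sequence[str],
                      target_class: str = "mRNA",
                      score_bearing: Sequence[str] = ()) -> pd.DataFrame:
    """Read one TSV per database and merge into one interaction table.

    Each file needs columns ``miRNA`` and ``target`` and may carry
    ``score``. Duplicate (miRNA, target) records within one database are
    collapsed to the first occurrence (logged).
    """
    if len(paths) != len(db_names):
        raise ValidationError(
            f"got {len(paths)} paths but {len(db_names)} database names"
        )
    frames = []
    for path, db in zip(paths, db_names):
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            continue
        if not {"miRNA", "target"} <= set(df.columns):
            raise ValidationError(f"{path}: expected columns miRNA, target")
        n0 = len(df)
        df = df.drop_duplicates(subset=["miRNA", "target"], keep="first")
        if len(df) < n0:
            logger.warning("%s: collapsed %d duplicate records", db, n0 - len(df))
        frames.append(pd.DataFrame({
            "mirna": df["miRNA"].astype(str),
            "target": df["target"].astype(str),
            "target_class": target_class,
            "source_db": db,
            "score": df["score"] if "score" in df.columns else float("nan"),
        }))
    if not frames:
        merged = pd.DataFrame(columns=["mirna", "target", "target_class", "source_db", "score"])
    else:
        merged = pd.concat(frames, ignore_index=True)
    return validate_interactions(merged, score_bearing=score_bearing)


def write_interactions(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={"mirna": "miRNA"})
    out.to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    rename = {"class": "rna_class", "log2FC": "log2fc"}
    df = df.rename(columns=rename)
    return validate_de_table(df[DE_COLUMNS])


def write_de_table(table: pd.DataFrame, path) -> None:
    out = table[DE_COLUMNS].rename(columns={"rna_class": "class", "log2fc": "log2FC"})
    out.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_clinical(df[CLINICAL_COLUMNS])


def write_clinical(table: pd.DataFrame, path) -> None:
    table[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``set_id <TAB> description <TAB> gene1 <TAB> ...``."""
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line {lineno}: fewer than 3 fields")
            set_id, description, *genes = fields
            genes = [g for g in genes if g]
            collection.add(GeneSet(set_id, description, frozenset(genes)))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            members = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.set_id}\t{gs.description}\t{members}\n")


def write_network(network: nx.Graph, path, fmt: str = "sif") -> None:
    """Export a ceRNA network for Cytoscape.

    ``fmt``: ``sif`` (source TAB interaction-kind TAB target), ``graphml``
    (nodes keep rna_class/direction attributes) or ``tsv`` (flat edge list
    with node annotations).
    """
    fmt = fmt.lower()
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in sorted(network.edges(data=True)):
                kind = data.get("kind", "interacts")
                # orient edges miRNA-last for lnc edges, miRNA-first for mRNA edges
                fh.write(f"{u}\t{kind}\t{v}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(
            (n, {k: v for k, v in d.items() if isinstance(v, (str, int, float, bool))})
            for n, d in network.nodes(data=True)
        )
        g.add_edges_from(
            (u, v, {k: w for k, w in d.items() if isinstance(w, (str, int, float, bool))})
            for u, v, d in network.edges(data=True)
        )
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        rows = []
        for u, v, data in sorted(network.edges(data=True)):
            rows.append({
                "source": u,
                "target": v,
                "kind": data.get("kind", ""),
                "source_class": network.nodes[u].get("rna_class", ""),
                "target_class": network.nodes[v].get("rna_class", ""),
            })
        pd.DataFrame(rows, columns=["source", "target", "kind", "source_class", "target_class"]) \
            .to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown network format: {fmt!r}")


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
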