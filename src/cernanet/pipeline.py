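"""End-to-end driver: simulate (optional) -> DE -> targets -> network ->
rank -> enrich -> survival, with every intermediate written as TSV.

The pipeline is configured by a :class:`PipelineConfig` (loadable from a
YAML file; unknown keys are rejected) and is fully deterministic given
the seed. Each stage's record tallies (genes screened, edges kept,
triplets assembled, node/edge counts) are logged, mirroring how such
analyses report their intermediate sizes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import de, io, targets, topology
from .enrichment import enrich
from .network import (
    assemble_triplets,
    build_network,
    build_pairs,
    network_summary,
    triplets_to_frame,
)
from .simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_gene_sets,
    simulate_interactions,
    simulate_survival,
)
from .survival import screen_prognostic
from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters in one (YAML-serialisable) place."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    lfc_threshold: float = 1.0
    adjp_threshold: float = 0.05
    score_db: str = "TargetScan"
    score_threshold: float = -0.1
    min_db: int = 2
    hub_threshold: int = 5
    top_k: int = 3
    enrich_alpha: float = 0.05
    survival_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        # one seed drives everything, including the simulation
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_raw) - sim_known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        if "db_names" in sim_raw:
            sim_raw["db_names"] = tuple(sim_raw["db_names"])
        config = cls(simulation=SimulationConfig(**sim_raw), **raw)
        config.simulation.seed = config.seed
        return config

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["simulation"]["db_names"] = list(data["simulation"]["db_names"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def run_full(config: PipelineConfig, outdir) -> dict:
    """Run the whole synthetic-data pipeline into ``outdir``.

    Returns a dict of the in-memory results keyed by stage; every
    intermediate is also written as TSV/SIF/GraphML under ``outdir``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.simulation.seed = config.seed
    config.to_yaml(out / "config.yaml")

    matrix, truth = simulate_counts(config.simulation)
    io.write_counts(matrix, out / "counts.tsv")
    mrna_table, lnc_table = simulate_interactions(truth, config.simulation)
    io.write_interactions(mrna_table, out / "targets_mrna.tsv")
    io.write_interactions(lnc_table, out / "targets_lnc.tsv")
    clinical = simulate_survival(matrix, truth, config.simulation)
    io.write_clinical(clinical, out / "clinical.tsv")

    de_table = de.test_differential(matrix)
    screened = de.screen(de_table, config.lfc_threshold, config.adjp_threshold)
    io.write_de_table(de_table, out / "de_all.tsv")
    io.write_de_table(screened, out / "de_screened.tsv")
    composition = de.summarize_directions(screened)
    composition.to_csv(out / "de_composition.tsv", sep="\t", index=False)
    logger.info("DE screen: %d/%d genes retained", len(screened), len(de_table))

    consensus = targets.build_consensus(
        mrna_table, lnc_table,
        score_db=config.score_db, score_threshold=config.score_threshold,
        min_db=config.min_db,
    )
    logger.info("consensus: %d miRNA-mRNA edges, %d miRNA-lncRNA edges",
                len(consensus.mirna_mrna), len(consensus.mirna_lnc))

    lnc_mi, mi_mrna = build_pairs(screened, consensus)
    triplets = assemble_triplets(lnc_mi, mi_mrna, screened)
    triplets_to_frame(triplets).to_csv(out / "triplets.tsv", sep="\t", index=False)
    net_up, net_down = build_network(triplets, screened)
    for name, net in (("lnc_up", net_up), ("lnc_down", net_down)):
        io.write_network(net, out / f"network_{name}.sif", "sif")
        io.write_network(net, out / f"network_{name}.graphml", "graphml")
        logger.info("network %s: %s", name, network_summary(net))

    rankings = {}
    key_lncrnas = {}
    for name, net in (("lnc_up", net_up), ("lnc_down", net_down)):
        ranked = topology.rank_lncrnas(net)
        ranked.to_csv(out / f"topology_{name}.tsv", sep="\t", index=False)
        rankings[name] = ranked
        key_lncrnas[name] = topology.select_key_lncrnas(ranked, k=config.top_k)
        hubs = topology.hub_nodes(net, threshold=config.hub_threshold)
        hubs.to_csv(out / f"hubs_{name}.tsv", sep="\t", index=False)

    # enrichment of network mRNAs against synthetic gene sets; universe =
    # all mRNAs in the full DE table
    universe = set(de_table.loc[de_table["rna_class"] == "mRNA", "gene"])
    network_mrnas = {n for net in (net_up, net_down)
                     for n, d in net.nodes(data=True) if d["rna_class"] == "mRNA"}
    collection = simulate_gene_sets(
        universe, config.seed + 3,
        enriched_genes=sorted({t[2] for t in truth.planted_triplets}),
    )
    io.write_gmt(collection, out / "gene_sets.gmt")
    enrichment_table = enrich(network_mrnas, collection, universe,
                              alpha=config.enrich_alpha)
    enrichment_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    network_genes = sorted(
        {n for net in (net_up, net_down) for n in net.nodes}
    )
    prognostic = screen_prognostic(matrix, clinical, network_genes,
                                   alpha=config.survival_alpha)
    prognostic.to_csv(out / "prognostic.tsv", sep="\t", index=False)

    return {
        "matrix": matrix,
        "truth": truth,
        "de_table": de_table,
        "screened": screened,
        "composition": composition,
        "consensus": consensus,
        "triplets": triplets,
        "network_up": net_up,
        "network_down": net_down,
        "rankings": rankings,
        "key_lncrnas": key_lncrnas,
        "enrichment": enrichment_table,
        "prognostic": prognostic,
    }
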