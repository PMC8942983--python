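import numpy as np
import pandas as pd
import pytest

from cernanet import de
from cernanet.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_gene_sets,
    simulate_interactions,
    simulate_survival,
)
from cernanet.targets import build_consensus
from cernanet.types import ValidationError

SMALL = dict(n_lnc=30, n_mirna=15, n_mrna=40, n_triplets=5)


class TestSimulateCounts:
    def test_seeded_determinism_bitwise(self):
        cfg = SimulationConfig(seed=1, **SMALL)
        m1, t1 = simulate_counts(cfg)
        m2, t2 = simulate_counts(cfg)
        assert m1.counts.equals(m2.counts)
        assert t1.planted_triplets == t2.planted_triplets

    def test_infeasible_planting_rejected_before_sampling(self):
        with pytest.raises(ValidationError, match="n_triplets"):
            simulate_counts(SimulationConfig(n_lnc=3, n_mirna=3, n_mrna=3,
                                             n_triplets=4))

    def test_planted_triplets_direction_consistent(self):
        _, truth = simulate_counts(SimulationConfig(seed=2, **SMALL))
        for lnc, mir, mrna in truth.planted_triplets:
            assert truth.planted_de[lnc] == truth.planted_de[mrna]
            assert truth.planted_de[mir] != truth.planted_de[lnc]
            assert truth.planted_de[mir] in ("up", "down")

    def test_overlap_planting_keeps_direction_consistency(self):
        cfg = SimulationConfig(seed=3, overlap_planting=True, n_triplets=8, **{
            k: v for k, v in SMALL.items() if k != "n_triplets"})
        _, truth = simulate_counts(cfg)
        assert truth.planted_triplets
        for lnc, mir, mrna in truth.planted_triplets:
            assert truth.planted_de[lnc] == truth.planted_de[mrna] != truth.planted_de[mir]

    def test_null_effect_keeps_distributions_identical(self):
        # directions are recorded but case/control means are equal, so a
        # BH-screened DE table retains essentially nothing
        cfg = SimulationConfig(seed=4, effect_log2fc=0.0, n_lnc=100,
                               n_mirna=50, n_mrna=150, n_triplets=5)
        matrix, truth = simulate_counts(cfg)
        assert set(truth.planted_de.values()) == {"up", "down", "null"}
        table = de.test_differential(matrix)
        screened = de.screen(table)
        assert len(screened) <= 0.01 * len(table)


class TestSimulateInteractions:
    @pytest.fixture
    def truth_and_cfg(self):
        cfg = SimulationConfig(seed=5, decoy_edges=20, **SMALL)
        _, truth = simulate_counts(cfg)
        return truth, cfg

    def test_planted_edges_supported_by_at_least_two_dbs(self, truth_and_cfg):
        truth, cfg = truth_and_cfg
        mrna_table, _ = simulate_interactions(truth, cfg)
        support = mrna_table.groupby(["mirna", "target"])["source_db"].nunique()
        for mirna, mrna in truth.true_mrna_edges:
            assert support[(mirna, mrna)] >= 2

    def test_forced_k3_appears_in_all_three_tables(self):
        cfg = SimulationConfig(seed=6, db_support={3: 1.0}, **SMALL)
        _, truth = simulate_counts(cfg)
        mrna_table, _ = simulate_interactions(truth, cfg)
        support = mrna_table.groupby(["mirna", "target"])["source_db"].nunique()
        for edge in truth.true_mrna_edges:
            assert support[edge] == 3

    def test_decoys_in_exactly_one_db_and_eliminated_by_consensus(self, truth_and_cfg):
        truth, cfg = truth_and_cfg
        mrna_table, lnc_table = simulate_interactions(truth, cfg)
        support = mrna_table.groupby(["mirna", "target"])["source_db"].nunique()
        decoys = set(support.index) - truth.true_mrna_edges
        assert len(decoys) == cfg.decoy_edges
        assert (support[list(decoys)] == 1).all()
        consensus = build_consensus(mrna_table, lnc_table)
        assert set(consensus.mirna_mrna).isdisjoint(decoys)

    def test_zero_decoys_consensus_recovers_true_edge_set_exactly(self):
        # ~50 true edges, no decoys: the consensus edge set is the truth
        cfg = SimulationConfig(seed=7, n_lnc=60, n_mirna=60, n_mrna=60,
                               n_triplets=50, decoy_edges=0)
        _, truth = simulate_counts(cfg)
        mrna_table, lnc_table = simulate_interactions(truth, cfg)
        consensus = build_consensus(mrna_table, lnc_table)
        assert set(consensus.mirna_mrna) == truth.true_mrna_edges
        assert consensus.mirna_lnc == truth.true_lnc_edges

    def test_targetscan_scores_true_below_cut_decoys_split(self):
        cfg = SimulationConfig(seed=8, decoy_edges=40, **SMALL)
        _, truth = simulate_counts(cfg)
        mrna_table, _ = simulate_interactions(truth, cfg)
        ts = mrna_table[mrna_table["source_db"] == "TargetScan"]
        true_rows = ts[[tuple(x) in truth.true_mrna_edges
                        for x in ts[["mirna", "target"]].to_numpy()]]
        decoy_rows = ts[[tuple(x) not in truth.true_mrna_edges
                         for x in ts[["mirna", "target"]].to_numpy()]]
        assert (true_rows["score"] < -0.1).all()
        if len(decoy_rows) >= 2:
            n_low = int((decoy_rows["score"] < -0.1).sum())
            assert abs(n_low - len(decoy_rows) / 2) <= 0.5

    def test_deterministic(self, truth_and_cfg):
        truth, cfg = truth_and_cfg
        a, al = simulate_interactions(truth, cfg)
        b, bl = simulate_interactions(truth, cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(al, bl)


class TestSimulateSurvival:
    def test_deterministic_and_schema_valid(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        matrix, truth = simulate_counts(cfg)
        a = simulate_survival(matrix, truth, cfg)
        b = simulate_survival(matrix, truth, cfg)
        pd.testing.assert_frame_equal(a, b)
        assert (a["time"] > 0).all()
        assert set(a["event"]) <= {0, 1}

    def test_censoring_fraction_near_default_30pct(self):
        cfg = SimulationConfig(seed=10, n_case=150, n_control=150, **{
            k: v for k, v in SMALL.items()})
        matrix, truth = simulate_counts(cfg)
        clin = simulate_survival(matrix, truth, cfg)
        censored = 1 - clin["event"].mean()
        assert 0.15 <= censored <= 0.45

    def test_null_hazard_flags_near_alpha(self):
        # all hazard log-ratios zero: the log-rank screen over planted
        # genes flags about alpha of them
        from cernanet.survival import screen_prognostic

        flags = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, hazard_log_ratio=0.0,
                                   n_case=50, n_control=50, **SMALL)
            matrix, truth = simulate_counts(cfg)
            clin = simulate_survival(matrix, truth, cfg)
            genes = list(matrix.gene_ids[:10])
            res = screen_prognostic(matrix, clin, genes)
            flags.extend(res["flagged"].tolist())
        rate = np.mean(flags)
        se = np.sqrt(0.05 * 0.95 / len(flags))
        assert rate <= 0.05 + 3 * se

    def test_planted_hazard_detected(self):
        # one strong prognostic gene, n=200: flagged in >= 90% of seeds
        from cernanet.survival import screen_prognostic

        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_prognostic=1,
                                   hazard_log_ratio=1.5,
                                   n_case=100, n_control=100, **SMALL)
            matrix, truth = simulate_counts(cfg)
            clin = simulate_survival(matrix, truth, cfg)
            gene = next(iter(truth.prognostic_genes))
            res = screen_prognostic(matrix, clin, [gene])
            hits += bool(res["flagged"].iloc[0])
        assert hits >= 9


class TestSimulateGeneSets:
    def test_seeded_and_enriched_seeding(self):
        universe = [f"G{i}" for i in range(100)]
        a = simulate_gene_sets(universe, 0, enriched_genes=["G1", "G2"])
        b = simulate_gene_sets(universe, 0, enriched_genes=["G1", "G2"])
        assert {s.set_id: s.genes for s in a} == {s.set_id: s.genes for s in b}
        assert {"G1", "G2"} <= a["SET000"].genes
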