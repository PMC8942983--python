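"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:

* two-group (case/control) RNA counts for three RNA classes, drawn from a
  negative binomial (an overdispersed Poisson) with gene-specific means
  and one shared dispersion;
* planted, direction-consistent ceRNA triplets — the lncRNA and mRNA
  shifted the same way between groups, the miRNA the opposite way;
* multi-database miRNA-target tables: every planted miRNA->mRNA edge is
  supported by at least two databases, decoy edges by exactly one, and
  the score-bearing (TargetScan-style) table scores true edges below the
  -0.1 cut while half of its decoys sit above it;
* survival times whose hazard depends log-linearly on planted prognostic
  genes, with uniform censoring.

Everything is driven by one integer seed; the same seed reproduces the
same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ValidationError,
    validate_interactions,
)

DEFAULT_DBS = ("miRDB", "miRTarBase", "TargetScan")


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Sizes default to a scaled-down two-cohort design: 20 case vs 20
    control samples per series, a few hundred genes per class, and ten
    planted triplets with a 2-fold-change-per-unit effect of 2 on the
    log2 scale (i.e. 4x shifts) — strong enough that a screened triplet
    is recoverable but not trivially so.
    """

    n_lnc: int = 200
    n_mirna: int = 60
    n_mrna: int = 300
    n_case: int = 20
    n_control: int = 20
    baseline_mean: float = 100.0
    dispersion: float = 0.2           # NB variance = mu + dispersion * mu^2
    n_triplets: int = 10
    effect_log2fc: float = 2.0
    decoy_edges: int = 30             # miRNA->mRNA decoys, single-db support
    decoy_lnc_edges: int = 0          # miRNA->lncRNA decoys (pass-through side)
    db_names: tuple = DEFAULT_DBS
    lnc_db_name: str = "starBase"
    db_support: dict = field(default_factory=lambda: {2: 0.5, 3: 0.5})
    overlap_planting: bool = False    # allow genes shared across triplets
    n_prognostic: int = 2
    hazard_log_ratio: float = 1.0
    censor_scale: float = 3.2         # uniform censoring horizon, x mean survival
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_lnc", "n_mirna", "n_mrna", "n_case", "n_control"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("baseline_mean and dispersion must be positive")
        cap = min(self.n_lnc, self.n_mirna, self.n_mrna)
        if not self.overlap_planting and self.n_triplets > cap:
            raise ValidationError(
                f"n_triplets={self.n_triplets} exceeds the disjoint planting "
                f"capacity min(n_lnc, n_mirna, n_mrna)={cap}"
            )
        if self.n_triplets < 0 or self.decoy_edges < 0:
            raise ValidationError("n_triplets and decoy_edges must be >= 0")
        if self.db_support and not all(k >= 2 for k in self.db_support):
            raise ValidationError("db_support must put all mass on >= 2 databases")
        if len(self.db_names) < max(self.db_support, default=2):
            raise ValidationError("db_support asks for more databases than db_names has")


@dataclass
class GroundTruth:
    """What was planted: the answer key for recovery tests."""

    planted_triplets: set            # {(lncrna, mirna, mrna)}
    planted_de: dict                 # gene -> "up" | "down" | "null"
    true_mrna_edges: set             # {(mirna, mrna)}
    true_lnc_edges: set              # {(mirna, lncrna)}
    prognostic_genes: dict           # gene -> hazard log-ratio


def _gene_ids(config: SimulationConfig) -> tuple:
    lncs = [f"LNC{i:04d}" for i in range(config.n_lnc)]
    mirs = [f"MIR{i:04d}" for i in range(config.n_mirna)]
    mrnas = [f"GENE{i:04d}" for i in range(config.n_mrna)]
    return lncs, mirs, mrnas


def _plant(config: SimulationConfig, rng: np.random.Generator) -> tuple:
    """Choose triplet members and directions; returns (triplets, planted_de)."""
    lncs, mirs, mrnas = _gene_ids(config)
    planted_de: dict = {}
    triplets = set()
    if config.overlap_planting:
        pool = max(2, int(np.ceil(config.n_triplets / 2)))
        lp, mp, gp = lncs[:pool], mirs[:pool], mrnas[:pool]
        seen = set()
        while len(triplets) < config.n_triplets:
            t = (rng.choice(lp), rng.choice(mp), rng.choice(gp))
            if t in seen:
                continue
            seen.add(t)
            triplets.add(t)
    else:
        for i in range(config.n_triplets):
            triplets.add((lncs[i], mirs[i], mrnas[i]))
    # lncRNA direction alternates so both network groups are populated
    for i, (lnc, mir, mrna) in enumerate(sorted(triplets)):
        lnc_dir = planted_de.get(lnc) or ("up" if i % 2 == 0 else "down")
        mir_dir = "down" if lnc_dir == "up" else "up"
        if planted_de.get(mir, mir_dir) != mir_dir or planted_de.get(mrna, lnc_dir) != lnc_dir:
            # under overlap planting a reused gene keeps its first direction;
            # drop direction-inconsistent triplets rather than emit them
            triplets = {t for t in triplets if t != (lnc, mir, mrna)}
            continue
        planted_de[lnc] = lnc_dir
        planted_de[mir] = mir_dir
        planted_de[mrna] = lnc_dir
    return triplets, planted_de


def simulate_counts(config: SimulationConfig) -> tuple:
    """Draw the genes x samples count matrix and its ground truth.

    Counts are negative binomial with lognormal gene-specific baseline
    means; a planted gene's case-group mean is shifted by +-effect_log2fc
    on the log2 scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lncs, mirs, mrnas = _gene_ids(config)
    genes = lncs + mirs + mrnas
    rna_class = pd.Series(
        ["lncRNA"] * len(lncs) + ["miRNA"] * len(mirs) + ["mRNA"] * len(mrnas),
        index=genes,
    )
    samples = [f"case{i:03d}" for i in range(config.n_case)] + \
              [f"ctrl{i:03d}" for i in range(config.n_control)]
    group = pd.Series(["case"] * config.n_case + ["control"] * config.n_control,
                      index=samples)

    triplets, planted_de = _plant(config, rng)
    base_mean = config.baseline_mean * rng.lognormal(0.0, 0.5, size=len(genes))
    shift = np.array([
        {"up": config.effect_log2fc, "down": -config.effect_log2fc}.get(
            planted_de.get(g, "null"), 0.0)
        for g in genes
    ])
    case_mean = base_mean * 2.0 ** shift

    size = 1.0 / config.dispersion  # NB "n" such that var = mu + mu^2/n
    counts = np.empty((len(genes), len(samples)))
    for j, s in enumerate(samples):
        mu = case_mean if group[s] == "case" else base_mean
        counts[:, j] = rng.negative_binomial(size, size / (size + mu))
    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        rna_class=rna_class, group=group,
    )
    planted_full = {g: planted_de.get(g, "null") for g in genes}
    truth = GroundTruth(
        planted_triplets=triplets,
        planted_de=planted_full,
        true_mrna_edges={(m, g) for (_l, m, g) in triplets},
        true_lnc_edges={(m, l) for (l, m, _g) in triplets},
        prognostic_genes=_pick_prognostic(config, triplets, genes),
    )
    return matrix, truth


def _pick_prognostic(config: SimulationConfig, triplets: set, genes: list) -> dict:
    if config.n_prognostic == 0:
        return {}
    ordered = sorted(triplets)
    candidates = [t[0] for t in ordered] + [t[2] for t in ordered]
    if not candidates:
        candidates = list(genes)
    chosen = list(dict.fromkeys(candidates))[: config.n_prognostic]
    return {g: config.hazard_log_ratio for g in chosen}


def simulate_interactions(truth: GroundTruth, config: SimulationConfig) -> tuple:
    """Emit the per-database target tables implied by the ground truth.

    Returns ``(mrna_table, lnc_table)`` in the merged interaction schema.
    True miRNA->mRNA edges get k supporting databases with k drawn from
    ``db_support`` (always >= 2); decoys get exactly one. TargetScan-style
    scores: true edges uniform in (-0.6, -0.15); decoys alternate between
    below and above the -0.1 cut.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    lncs, mirs, mrnas = _gene_ids(config)
    score_db = "TargetScan" if "TargetScan" in config.db_names else None

    ks = sorted(config.db_support)
    probs = np.array([config.db_support[k] for k in ks], dtype=float)
    probs /= probs.sum()

    records = []

    def add(mirna, target, db, score=np.nan):
        records.append((mirna, target, "mRNA", db, score))

    for mirna, mrna in sorted(truth.true_mrna_edges):
        k = int(rng.choice(ks, p=probs)) if ks else 2
        dbs = list(rng.choice(config.db_names, size=k, replace=False))
        if score_db in dbs:
            add(mirna, mrna, score_db, float(rng.uniform(-0.6, -0.15)))
            dbs.remove(score_db)
        for db in dbs:
            add(mirna, mrna, db)

    # decoys: single-database support, never colliding with a true edge
    existing = set(truth.true_mrna_edges)
    n_decoys = 0
    low_score = True
    while n_decoys < config.decoy_edges:
        pair = (str(rng.choice(mirs)), str(rng.choice(mrnas)))
        if pair in existing:
            continue
        existing.add(pair)
        db = str(rng.choice(config.db_names))
        if db == score_db:
            score = float(rng.uniform(-0.6, -0.15)) if low_score else float(rng.uniform(-0.1, 0.3))
            low_score = not low_score
            add(pair[0], pair[1], db, score)
        else:
            add(pair[0], pair[1], db)
        n_decoys += 1

    mrna_table = pd.DataFrame(
        records, columns=["mirna", "target", "target_class", "source_db", "score"]
    )

    lnc_records = [
        (mirna, lnc, "lncRNA", config.lnc_db_name, np.nan)
        for mirna, lnc in sorted(truth.true_lnc_edges)
    ]
    existing_lnc = set(truth.true_lnc_edges)
    n_decoys = 0
    while n_decoys < config.decoy_lnc_edges:
        pair = (str(rng.choice(mirs)), str(rng.choice(lncs)))
        if pair in existing_lnc:
            continue
        existing_lnc.add(pair)
        lnc_records.append((pair[0], pair[1], "lncRNA", config.lnc_db_name, np.nan))
        n_decoys += 1
    lnc_table = pd.DataFrame(
        lnc_records, columns=["mirna", "target", "target_class", "source_db", "score"]
    )
    score_bearing = (score_db,) if score_db else ()
    return (validate_interactions(mrna_table, score_bearing=score_bearing),
            validate_interactions(lnc_table))


def simulate_survival(matrix: ExpressionMatrix, truth: GroundTruth,
                      config: SimulationConfig) -> pd.DataFrame:
    """Exponential survival with log-hazard linear in prognostic expression.

    Per-sample log-hazard is the sum over prognostic genes of the hazard
    log-ratio times the standardised log2(CPM+1) expression. Censoring is
    uniform on (0, censor_scale x mean survival), which at the default 3.2
    yields roughly 30% censoring.
    """
    rng = np.random.default_rng(config.seed + 2)
    from .de import cpm  # local import to avoid a cycle at module load

    log_expr = np.log2(cpm(matrix.counts) + 1.0)
    loghaz = np.zeros(len(matrix.sample_ids))
    for gene, beta in truth.prognostic_genes.items():
        x = log_expr.loc[gene].to_numpy()
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        loghaz += beta * z
    scale = np.exp(-loghaz)  # mean survival per sample
    t = rng.exponential(scale)
    cmax = config.censor_scale * float(scale.mean())
    c = rng.uniform(0.0, cmax, size=len(t))
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({
        "sample": list(matrix.sample_ids),
        "time": time,
        "event": event,
    })


def simulate_gene_sets(universe, rng_or_seed=0, n_sets: int = 20,
                       min_size: int = 5, max_size: int = 30,
                       enriched_genes=(), n_enriched_sets: int = 2) -> GeneSetCollection:
    """Random gene sets over ``universe`` for exercising the ORA stage.

    ``n_enriched_sets`` sets are seeded with ``enriched_genes`` (e.g. the
    planted triplet mRNAs) so a recovered network has something to enrich
    for; the rest are uniform draws.
    """
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    universe = sorted(universe)
    if not universe:
        raise ValidationError("empty universe for gene-set simulation")
    enriched = [g for g in enriched_genes if g in set(universe)]
    collection = GeneSetCollection()
    for i in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        members = set(rng.choice(universe, size=min(size, len(universe)), replace=False))
        if i < n_enriched_sets and enriched:
            members |= set(enriched)
        collection.add(GeneSet(f"SET{i:03d}", f"synthetic set {i}", frozenset(members)))
    return collection


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
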