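# Methods

## The inference model

The package operationalises the ceRNA hypothesis at the level of
*direction-opposed differential expression*: a competing triplet
(lncRNA, miRNA, mRNA) requires (i) the miRNA to target both the lncRNA
and the mRNA according to sequence-based prediction databases, (ii) all
three genes to pass the DE screen, and (iii) the lncRNA and mRNA to be
dysregulated in the same direction and the miRNA in the opposite one.
"Negatively co-expressed" is deliberately *not* implemented as a
sample-level correlation coefficient by default: the three RNA classes
are typically profiled in different cohorts (separate lncRNA/mRNA and
miRNA series), so cross-sample correlation is not computable there.
Direction opposition is the executable reading of negative co-expression
in that design. For same-cohort data, `build_pairs` accepts an
expression matrix and a `min_neg_corr` flag that additionally requires a
negative Pearson correlation of log2(CPM+1) profiles.

Triplets are partitioned by the lncRNA's DE direction into an
lncRNA-up and an lncRNA-down group and each group is unioned into one
tripartite network. A miRNA or mRNA may appear in both group networks;
the partition is over triplets, not genes.

## Differential expression

The built-in test is a simple surrogate, not a negative-binomial GLM:
counts-per-million normalisation, log2(x+1) transform, two-sided Welch
t-test per gene, Benjamini–Hochberg adjustment *within each RNA class*
(the classes come from separate experiments and are screened
separately). Fold change is `log2((mean case CPM + 1)/(mean control CPM
+ 1))` with the case group in the numerator. Screening keeps genes with
|log2FC| > 1 AND adjusted p < 0.05, both strict inequalities. The
surrogate is deterministic and adequate for synthetic negative-binomial
data (its null false-positive rate is checked in the test suite); for
real data, externally computed DE tables (edgeR, DESeq2, limma) can be
imported through `merge_external_de` / `io.read_de_table`, which is the
intended path. Empirical-Bayes dispersion moderation is a non-goal.
Genes with identical values in both groups get p = 1 (a zero-variance
t-statistic is treated as no evidence, not an error).

## Target-prediction consensus

"Supported by at least two databases" counts *distinct database names*,
never record multiplicity within one export. The score-bearing
(TargetScan-style) table is filtered to context scores strictly below
−0.1 *before* support counting, so a sub-threshold record cannot serve
as second support — the stricter of the two possible orderings. The
miRNA→lncRNA side has no consensus rule (a single starBase-style
source); this asymmetry is intentional. Database names are data, not
code: real exports can be substituted by naming them in the readers.

## Topology

* Degree is the number of distinct incident edges.
* Hub rule: degree **strictly greater than** 5 by default
  (configurable); "exceeding" is read as strict.
* Secondary pairs count distinct miRNA–mRNA *edges*, not paths: an mRNA
  reachable through two miRNA neighbours contributes two pairs. With
  this reading total = first + secondary holds identically.
* Key-lncRNA rule: the intersection of the top-*k* by degree and the
  top-*k* by total pairs (k = 3 by default). The rule may return fewer
  than *k* genes, and an empty intersection is a warning, not an error.
* All orderings break ties by total pairs and then lexicographically by
  gene id, making every ranking deterministic.
* A lncRNA's sub-network is the induced subgraph on the lncRNA, its
  miRNA neighbours and those miRNAs' mRNA neighbours; extraction is
  idempotent and its mRNA set is the enrichment query for that lncRNA.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) per gene set, computed via
`scipy.stats.hypergeom.sf` (verified against exhaustive subset
enumeration for all universes up to N = 12 in the tests). The
significance flag uses the raw p-value at α = 0.05 — matching the usual
ORA screening convention — while BH-adjusted p-values are always
reported alongside, because raw-p screening inflates findings. The
default universe is the caller's choice; the pipeline uses all mRNAs in
the unscreened DE table. Gene-set hierarchies (GO parent/child) are
ignored; sets are flat.

## Survival

Median split assigns samples at the median to "low" (a deterministic
tie rule; the conventional web tools do not publish theirs), and a
degenerate split (constant expression) yields NaN rather than a test.
Kaplan–Meier estimation and the two-group log-rank test are delegated
to lifelines; the tests check them against hand-computed product-limit
and O/E/V tables. The per-gene screen applies no multiple-testing
correction across genes — mirroring common practice for this screen —
and the output documents itself as uncorrected raw p-values.

## qPCR arithmetic

Replicates are averaged at the Ct level before ΔCt (standard practice);
ΔΔCt subtracts the *mean* control ΔCt, so control fold changes centre
on 1 in log space. Group comparison defaults to the equal-variance
Student t-test, with Welch available behind a flag. Amplification-
efficiency correction is out of scope.

## Synthetic data

The generator emulates the assumed data structure, not the biology:

* **Counts**: negative binomial with variance μ + φμ² and one shared
  dispersion φ = 0.2; gene baseline means are lognormal around 100.
  Planted genes shift the case-group mean by ±`effect_log2fc` (default
  2) on the log2 scale. Default design: 20 case vs 20 control samples,
  200 lncRNAs / 60 miRNAs / 300 mRNAs, 10 planted triplets — a
  deliberately scaled-down cohort that keeps every simulation-backed
  test fast while leaving hundreds of null genes per class for error
  calibration. Published per-series sample sizes were not available to
  copy, so 20 + 20 is the package's stated default design.
* **Planting**: disjoint by default (each gene in at most one triplet)
  for unambiguous recovery scoring; lncRNA directions alternate so both
  network groups are populated; `overlap_planting=True` allows shared
  genes, dropping direction-inconsistent combinations.
* **Target tables**: every planted miRNA→mRNA edge is supported by
  k ≥ 2 databases (k drawn from `db_support`, default 50/50 over
  {2, 3}); decoys get exactly one database. TargetScan-style scores:
  true edges uniform in (−0.6, −0.15); decoys alternate below/above the
  −0.1 cut so both the score filter and the consensus rule are
  exercised.
* **Survival**: exponential times with per-sample log-hazard
  Σ β·z(gene), z the standardised log2(CPM+1) expression; censoring is
  uniform on (0, 3.2 × mean survival), chosen because
  (1 − e^(−x))/x = 0.3 at x ≈ 3.2, i.e. ≈ 30 % censoring — a typical
  AML-cohort fraction. Note that with two planted prognostic genes of
  opposite DE direction the cohort-level hazard signals partly cancel;
  power statements in the tests therefore use a single planted gene.
* **Gene sets**: uniform random sets over the mRNA universe, with a
  configurable number seeded by the planted triplet mRNAs so the
  pipeline's enrichment stage has true structure to find.

What passing on synthetic data does **not** show: robustness to
library-composition bias, batch effects, probe-level noise, annotation
ambiguity, or realistic miRNA-target score distributions — the
generator draws none of these.

## Numerical and interface choices

* All tabular I/O is TSV (UTF-8, header row); networks export as SIF,
  GraphML and flat edge TSV for Cytoscape. Readers reject schema
  violations loudly and log any records they exclude.
* Gene identifiers are opaque case-sensitive strings; no alias
  resolution.
* Every stochastic component takes a single integer seed;
  `PipelineConfig.seed` propagates to the simulation, and identical
  seeds give byte-identical pipeline outputs.
* `scripts/acceptance.py` re-derives its reported quantities at run
  time: the composition percentages from the built-in class counts, the
  ranking quantities from the expanded profile network, and the
  recovery/error/power figures from fresh seeded simulations (10
  recovery seeds, 3 null-DE seeds of 560 genes, 10 log-rank power
  replicates at 100 subjects per arm).

## Known limitations

* The DE surrogate is not edgeR; on real overdispersed data import the
  dedicated tool's output instead.
* Only two-arm survival comparisons are supported; no Cox regression.
* The enrichment module tests flat sets only; term-term relationships
  and kappa-grouping are out of scope.
* The ranking fixture encodes published summary counts; the expanded
  fixture network around them is synthetic (private miRNA/mRNA
  partners), so node identities beyond the lncRNAs are placeholders.
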