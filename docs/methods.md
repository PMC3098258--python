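# Methods

`gpnet` rebuilds gene–gene and phenotype–phenotype association networks
from ontology-annotated gene–phenotype data and characterises their
modular structure. This note documents the model, the parameters that
matter, the numerical choices, what the synthetic data emulate, and the
known limitations.

## From annotations to the weighted biadjacency matrix

Inputs are (gene, term) association pairs against a rooted ontology DAG
(is_a links only; obsolete terms dropped at parse time). Zygosity and
allele detail are collapsed: any genotype of a gene showing a phenotype
associates the gene with the term, so records deduplicate on the
(gene, term) pair. Absence of a record is treated as "no data", never as
"phenotype absent". Uninformative terms ("normal phenotype", "no
phenotypic analysis", and four reversion/no-analysis variants) are
removed by default.

The *level* of a term is the length of the shortest path from the root;
the root's children are level 1. For a multi-parent term the shortest
path decides, which matches the usual ontology-level convention and is
deterministic. Annotation usage in curated corpora peaks at
intermediate levels, so the analysis fixes a working level `L`
(default 5, with 8 as a more granular alternative).

Each term `j` receives a granularity weight derived from `n_j`, the
number of its strict descendants carrying at least one annotation in
the data set:

    g_j = 1 / (1 + n_j)        (scheme "inverse", default)
    g_j = 1 + n_j              (scheme "linear")

The inverse scheme down-weights broad terms so that specific annotations
dominate; the linear scheme is retained because the prose convention for
"granularity" can be read in either direction, and the choice is
recorded in run metadata.

The weighted biadjacency matrix `B` at level `L` has one row per gene
and one column per level-L term with at least one annotation below it:

    B_ij = sum over t in T_ij of g_t

where `T_ij` is the set of annotated terms of gene `i` that are
descendants-or-self of column term `j`. A term exactly at level L counts
as its own descendant-or-self (configurable), so level-L annotations are
not discarded. Multi-parent terms contribute to every qualifying
column. All-zero columns are dropped; row/column order is lexicographic.

## The association score d

For a gene pair (i1, i2) and a column `j`, let `u` and `v` be the two
genes' granularity-weight vectors over the data-set-annotated
descendant-or-self terms of `j` (zero where a gene lacks the term). The
per-phenotype similarity is the two-sided two-sample Wilcoxon rank-sum
p-value of `u` against `v`: identical annotation profiles give p = 1,
strongly different annotation loads give small p. A column carries
signal for a pair only when **both** genes are annotated under it; this
gate makes d exactly zero for pairs sharing no level-L phenotype, which
the thresholding step relies on. (The alternative gate, scoring columns
where only one gene is annotated, is available as `gate="either"`.)

Because the rank-sum statistic is position-blind, the score measures
similarity of annotation *depth and load* under `j`, not which specific
descendant terms were used — two genes annotated to disjoint but equally
weighted terms under the same column score as similar. This is the
intended granularity-level semantics of the construction.

The pooled pair×phenotype p-values are corrected with
Benjamini–Hochberg (a Benjamini–Yekutieli option exists), and the final
score is the mean over **all** level-L columns,

    d_{i1i2} = (1 / n_columns) * sum over signal columns of q,

so d lies in [0, 1] and is symmetric. With hundreds of columns and a
handful of shared phenotypes per pair, d values land on the 10^-3–10^-2
scale, which is why the shipped network cutoffs are of that order
(gene networks 0.009 at L=5 and 0.011 at L=8; phenotype networks 0.005
and 0.002). For data without an externally chosen cutoff,
`suggest_cutoff` automates the by-inspection rule as an upper quantile
(default 0.9) of the nonzero d distribution.

Exact rank-sum nulls are used for tie-free samples with at most 10
observations per side; otherwise the normal approximation with tie and
continuity correction applies (the same fallback rule R's `wilcox.test`
uses). Fully degenerate comparisons (every value tied) return p = 1.
The phenotype–phenotype network is literally the gene pipeline run on
the transposed biadjacency matrix.

## Topology diagnostics and the rewiring null

Degree distributions P(k), degree-conditioned clustering C(k) and their
log–log regression slopes (gamma_hat = −slope of log P(k) on log k) are
computed on the binarized network, unbinned; fits are skipped and
flagged when fewer than three distinct positive degrees exist. The
rewiring null performs repeated double-edge swaps (default 10 per
edge), rejecting self-loops and multi-edges, which preserves every
node's degree exactly; observed mean clustering and modularity are
compared with the null ensemble via the empirical tail fraction
#{null ≥ observed}/n_reps. The same tail-fraction convention is used for
the PPI count comparison below, so a statistic exceeding every null
replicate reports 0 at the resolution of the replicate count.

## Community extraction

Communities come from recursive spectral bisection of the modularity
matrix `B = A − k kᵀ/2m`: each group is split along the sign pattern of
the leading eigenvector of its generalized modularity matrix, a split is
accepted only when it increases Q, and a Kernighan–Lin-style single-node
fine-tuning pass (enabled by default) follows each division. Connected
components are processed independently. Determinism: nodes are ordered
lexicographically, eigenvector sign ambiguity is resolved by placing the
lexicographically smallest node of a group on the + side, and zero
eigenvector entries join the + side. Detection runs on the binarized
graph (a weighted variant sits behind a flag). Hubs are nodes with
degree strictly above the 80th percentile of the degree distribution.

## Enrichment battery

Every enrichment compares within-community gene-pair values against a
control built from pseudo-communities of the same sizes resampled
(without replacement within a pseudo-community, independently across
replicates, default n_boot = 1000) from the analysed network's gene
set:

- **Expression, tissue and phylogenetic-profile similarity** use
  Pearson correlation matrices (genes × samples, binary genes × tissues,
  and integer genes × species copy numbers respectively); the within and
  control vectors are compared with a one-sided (within > control)
  two-sample Wilcoxon test. Undefined correlations from constant
  profiles are excluded pairwise.
- **Protein–protein interactions** keep only physical evidence types
  (the 14 standard experimental systems, e.g. Two-Hybrid, Affinity
  Capture-MS; genetic evidence such as Dosage Rescue is dropped) and
  compare the observed within-community interaction count against the
  null counts by empirical tail fraction.
- **GO similarity** reruns the full d pipeline on each GO branch's
  biadjacency matrix (default levels: BP 5, CC 5, MF 2) and feeds the
  resulting gene×gene d matrix through the same within-vs-control
  comparison.
- **Hub GO over-representation** tests each term's 2×2 hub/non-hub ×
  has/lacks table with a one-tailed Fisher exact test against the global
  network background, BH-corrected.
- **Level-1 term sharing**: for every gene pair the number of shared
  level-1 terms (both biadjacency entries positive) is binned
  {0, 1, 2, ≥3}; the 2×4 table of within-community pairs against all
  pairs gives a 3-degree-of-freedom chi-square, alongside the fractions
  of pairs sharing at least one term. The four-bin layout is one
  reconstruction of a 3-dof design and is configurable.

One-sided alternatives are used throughout because the planted/claimed
direction is enrichment, never depletion.

## Community-to-group mapping and cross-network comparison

Each gene is assigned to its highest-scoring level-1 term in the
level-1 biadjacency matrix (ties and all-zero rows are sentinel-marked
and belong to no group). The overlap of a community (size x) and a
group (size y) within a universe of N genes is scored by the law of the
intersection of two independent uniform subsets,

    P(Z = z) = C(x, z) C(N−x, y−z) / C(N, y),

with the tail P(Z ≥ z_obs) as the p-value, displayed as −log p. The
universe is the set of genes both partitioned and present in the
level-1 matrix. Cross-partition comparison computes the same tail
probability, or the symmetric overlap fraction (z/x + z/y)/2, for every
community pair, translating the second partition's identifiers through
an optional orthology table first. Heat-map row ordering uses
hierarchical clustering of the −log p rows with Euclidean distances.

## Phenotype clustering with multiscale bootstrap

Level-1 term columns of the biadjacency matrix are clustered with
average linkage on 1 − Pearson correlation (constant columns get
distance 1 with a warning). Support values come from multiscale
bootstrap: rows (genes) are resampled with replacement at scales
r ∈ {0.5, 0.6, …, 1.4} of the row count, n_boot (default 10^4) split
evenly across scales; BP_r is the per-scale fraction of replicates
reproducing each observed cluster, and the approximately unbiased value
extrapolates across scales by weighted least squares on

    qnorm(1 − BP_r) ≈ v √r + c / √r,    AU = Φ(c − v),

with delta-method binomial weights. Clusters with no usable cross-scale
variation (BP of 0 or 1 everywhere, or fewer than two interior scales)
fall back to AU = BP; the root cluster has support 1 by definition.
Rows, not columns, are resampled because the uncertainty of interest is
over the gene sample that induces the term–term correlations.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not mouse biology:

- a rooted DAG with `n_level1` level-1 subtrees (default 8), per-node
  Poisson branching (default mean 1.9) to depth 8, a guaranteed spine so
  every subtree reaches full depth (~1500 terms at the defaults), and
  extra same-subtree parents at rate 0.05 to create multi-parent
  diamonds without disturbing levels or subtree disjointness;
- gene modules (default 5 modules over 300 genes) each tied to a
  distinct level-1 subtree; each gene draws ~Poisson(8) annotations from
  its own subtree with probability `module_fidelity` (default 0.9), from
  another subtree otherwise, at depths peaked around level 5; each
  annotation is independently replaced by a uniform random term at the
  `pleiotropy_noise_rate` (default 0.05);
- auxiliary data planted per module: a shared-factor expression model
  (within-module correlation 0.6 over 200 samples), module-biased
  Bernoulli tissue profiles (30 tissues, 5 preferred per module at rate
  0.8 vs background 0.15), two-density Erdős–Rényi PPI blocks (0.10
  within, 0.01 between, plus decoy genetic-evidence rows that the
  physical filter must remove), latent-factor integer phylogenetic
  profiles over 40 species, and three GO branches generated by the same
  DAG machinery (BP/CC to depth 6 analysed at level 5, MF to depth 3
  analysed at level 2).

`null_bundle` keeps the marginals (including the pooled PPI density)
but removes every planted dependence, and `resample_auxiliary` redraws
the auxiliary data under either regime with the ontology, annotations
and labels held fixed — the tool used for calibration studies. All
randomness flows from one mandatory seed and bundles are byte-identical
across runs with the same seed.

What the synthetic data do **not** emulate: realistic annotation-depth
distributions beyond the single level-5 peak, literature ascertainment
bias, correlated pleiotropy between related phenotype domains, or
scale-free degree structure of the underlying biology. Passing the
planted-recovery tests therefore shows the pipeline recovers the kind
of modular signal it models, not that real curated corpora contain such
signal.

## Problem sizes used in tests and the acceptance script

The shipped study conditions are 300 genes in 5 modules with fidelity
0.9 and noise 0.05. The test suite runs resampling controls at
n_boot = 200 (and 50 for the 200-replicate calibration ensemble, whose
auxiliary data are regenerated independently each replicate), the
rewiring null at its full 1000 replicates, and phenotype-cluster
support at n_boot = 1000 (5000 for the seed-stability check). The
acceptance script uses the full defaults: n_boot = 1000, 1000 rewiring
replicates and 10^4 bootstrap resamples.

## Known limitations

- The pooled pair×phenotype FDR correction treats dependent tests as
  exchangeable; the BY option is provided for a dependence-robust
  alternative but is not the default.
- The rank-sum similarity is position-blind within a column (see above);
  semantic-similarity kernels are deliberately out of scope.
- The hypergeometric group-assignment p-values are reported raw, as
  −log p, without multiplicity calibration across the community×group
  grid.
- Spectral bisection with fine-tuning is deterministic but greedy; it
  can over-split weakly modular graphs relative to the global optimum,
  which only exhaustive search certifies (and is tested at n = 12).
- AU values inherit the usual multiscale-bootstrap caveats for clusters
  whose BP saturates at 0 or 1 on every scale; those fall back to BP.
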