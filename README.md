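# gpnet — gene–phenotype network analysis

`gpnet` builds and analyses association networks from ontology-annotated
gene–phenotype data, in the style of the mouse gene–phenotype network:
genes linked by the phenotypes they share, and phenotypes linked by the
genes they share. It is written for computational biologists who have a
bipartite gene↔term edge list against a phenotype ontology (e.g. the
Mammalian Phenotype ontology) and want to go from raw annotations to
communities, their functional characterisation, and their mapping to
high-level phenotype groups — without any external services.

## The method in brief

From an OBO ontology and a (gene, term) association list, the pipeline:

1. assigns every term its level (shortest path from the root) and a
   granularity weight g_j = 1/(1+n_j), where n_j counts annotated
   descendants, then builds the weighted biadjacency matrix at a chosen
   level L: B_ij = Σ_{t ∈ T_ij} g_t over gene i's annotated terms below
   column term j;
2. scores every gene pair per phenotype with a two-sided two-sample
   Wilcoxon rank-sum test on the two granularity-weight vectors,
   BH-corrects the pooled p-values, and averages over all level-L
   columns to get the association score d ∈ [0, 1] (columns not shared
   by the pair contribute 0); the phenotype network is the same
   pipeline on Bᵀ;
3. thresholds d at a cutoff (shipped defaults 0.009/0.011 for gene
   networks at L = 5/8 and 0.005/0.002 for phenotype networks, or an
   upper-quantile rule) and extracts communities by Newman's spectral
   method (leading eigenvector of the modularity matrix, recursive
   bisection with Kernighan–Lin refinement);
4. characterises the result: degree-distribution exponent γ and C(k)
   hierarchy, degree-preserving rewiring nulls for clustering and
   modularity Q, enrichment of communities for coexpression, tissue
   co-expression, physical protein–protein interactions, GO annotation
   similarity (the same d machinery on GO branches) and phylogenetic
   profile correlation against size-matched resampled controls,
   hub GO over-representation (one-tailed Fisher), and level-1
   term-sharing chi-square;
5. maps communities to level-1 phenotype groups through the
   hypergeometric intersection law P(Z = z) = C(x,z)C(N−x,y−z)/C(N,y)
   (reported as −log p), compares community sets across networks by
   tail probability or mean overlap fraction (z/x + z/y)/2, and
   clusters level-1 phenotypes by gene sharing (1 − Pearson, average
   linkage) with multiscale-bootstrap AU/BP support values.

A fully seeded synthetic-data module generates ontologies, annotations
and all auxiliary matrices with planted module structure (or a matched
structureless null), so every stage is testable offline. See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from gpnet import SyntheticConfig, generate, PipelineParams, run_all

bundle = generate(SyntheticConfig(seed=1))          # 300 genes, 5 planted modules
result = run_all(bundle, PipelineParams(n_boot=200, run_rewire=False,
                                        phen_n_boot=1000, seed=7))
s = result.summary
print(f"network: {s['n_network_nodes']:.0f} genes, {s['n_network_edges']:.0f} edges "
      f"(d_cutoff={s['d_cutoff']:.4f})")
print(f"communities: {s['n_communities']:.0f}  Q={s['modularity_Q']:.3f}  "
      f"ARI vs planted modules={s['community_ari_vs_planted']:.3f}")
```

prints

```
network: 288 genes, 2891 edges (d_cutoff=0.0187)
communities: 5  Q=0.709  ARI vs planted modules=0.948
enrichment p (expression, tissue, PPI, GO-BP, phylo): 0, 0, 0, 0, 0
level-1 sharing: 1.00 within vs 0.55 overall (chi2=5729)
```

(the last two lines from the analogous `print` calls on the enrichment
and contingency summaries). Reading: the d threshold keeps 288 of 300
genes; spectral extraction recovers the five planted modules almost
exactly (adjusted Rand index 0.948) at modularity Q = 0.709; within
recovered communities every tested functional signal is stronger than
in size-matched resampled controls (one-sided p below the resampling
resolution, reported as 0), and all within-community gene pairs share a
level-1 phenotype versus 55% of pairs overall.

The same analysis is scriptable from the shell:

```bash
gpnet simulate --seed 1 --out bundle/
gpnet all --bundle bundle/ --seed 7 --out run/      # writes TSV/GraphML/Newick + summary.json
```

Real data enter through the same door: `gpnet build-network --obo
MPheno.obo --annotations pairs.tsv --level 5 --cutoff 0.009 --out net/`
accepts any two-column gene/term TSV (column indices configurable),
with optional ID-mapping tables and exclusion lists.

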