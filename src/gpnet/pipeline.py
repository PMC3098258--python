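"""End-to-end orchestration of the gene-phenotype network analysis.

``run_all`` chains the stages on one input bundle and one parameter set:
biadjacency construction, gene / phenotype association matrices,
network thresholding, topology diagnostics (optionally with rewiring
nulls), spectral communities, the enrichment battery, community-to-group
mapping and level-1 phenotype clustering.  Every stochastic stage
derives its seed from the single run seed, so identical config + seed
gives byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import association, communities, community_mapping, enrichment, topology
from .biadjacency import build_biadjacency
from .phenotype_clustering import bootstrap_support
from .synthetic_data import Bundle

__all__ = ["PipelineParams", "PipelineResult", "run_all"]


@dataclass(frozen=True)
class PipelineParams:
    level: int = 5
    cutoff: Optional[float] = None  # explicit d_cutoff; else quantile rule
    cutoff_quantile: float = 0.9
    phen_cutoff: Optional[float] = None
    correction: str = "bh"
    granularity_scheme: str = "inverse"
    n_boot: int = 1000
    rewire_reps: int = 1000
    swaps_per_edge: int = 10
    phen_n_boot: int = 10000
    hub_percentile: float = 80.0
    seed: int = 0
    run_rewire: bool = True
    run_phenotype_network: bool = True
    run_phenotype_clustering: bool = True


@dataclass
class PipelineResult:
    params: PipelineParams
    B: object
    B1: object
    gene_assoc: object
    gene_net: object
    partition: object
    profile: object
    summary: Dict[str, float] = field(default_factory=dict)
    phen_assoc: object = None
    phen_net: object = None
    phen_partition: object = None
    rewiring: object = None
    enrichments: Dict[str, object] = field(default_factory=dict)
    group_assignments: object = None
    group_matrix: object = None
    contingency: object = None
    hub_table: object = None
    dendrogram: object = None


def _seed_for(base: int, stage: str) -> int:
    # stable per-stage sub-seed, kept below 2**31
    h = int.from_bytes(stage.encode(), "big") % 100003
    return int(np.random.SeedSequence([base, h]).generate_state(1)[0] % (2**31))


def run_all(bundle: Bundle, params: PipelineParams = PipelineParams(),
            outdir=None) -> PipelineResult:
    """Run the full analysis on a bundle; optionally write artifacts."""
    ann = bundle.annotations
    dag = bundle.dag

    B = build_biadjacency(ann, dag, params.level,
                          granularity_scheme=params.granularity_scheme)
    B1 = build_biadjacency(ann, dag, 1,
                           granularity_scheme=params.granularity_scheme)

    gene_assoc = association.pairwise_association(B, correction=params.correction)
    cutoff = params.cutoff
    if cutoff is None:
        cutoff = association.suggest_cutoff(gene_assoc, params.cutoff_quantile)
    gene_net = association.build_network(gene_assoc, cutoff)
    partition = communities.newman_spectral(gene_net)
    profile = topology.degree_profile(gene_net)

    summary: Dict[str, float] = {
        "n_genes_annotated": float(len(B.row_ids)),
        "n_columns_level": float(len(B.col_ids)),
        "d_cutoff": float(cutoff),
        "n_network_nodes": float(len(gene_net.nodes)),
        "n_network_edges": float(len(gene_net.edges)),
        "n_communities": float(partition.n_communities),
        "modularity_Q": float(partition.Q),
    }
    if profile.gamma_hat is not None:
        summary["gamma_hat"] = float(profile.gamma_hat)
        summary["fit_r2"] = float(profile.fit_r2)

    result = PipelineResult(
        params=params, B=B, B1=B1, gene_assoc=gene_assoc,
        gene_net=gene_net, partition=partition, profile=profile,
        summary=summary,
    )

    if bundle.labels:
        from sklearn.metrics import adjusted_rand_score

        common = [g for g in gene_net.nodes if g in bundle.labels]
        if len(common) >= 2:
            ari = adjusted_rand_score(
                [bundle.labels[g] for g in common],
                [partition.labels[g] for g in common],
            )
            summary["community_ari_vs_planted"] = float(ari)

    if params.run_phenotype_network:
        phen_assoc = association.pairwise_association(
            B.transpose(), correction=params.correction
        )
        pc = params.phen_cutoff
        if pc is None:
            pc = association.suggest_cutoff(phen_assoc, params.cutoff_quantile)
        phen_net = association.build_network(phen_assoc, pc)
        result.phen_assoc = phen_assoc
        result.phen_net = phen_net
        if phen_net.edges:
            result.phen_partition = communities.newman_spectral(phen_net)
            summary["n_phen_communities"] = float(result.phen_partition.n_communities)
            summary["phen_modularity_Q"] = float(result.phen_partition.Q)

    if params.run_rewire and len(gene_net.edges) >= 2:
        rew = topology.rewire_null(
            gene_net, n_reps=params.rewire_reps,
            swaps_per_edge=params.swaps_per_edge,
            seed=_seed_for(params.seed, "rewire"),
        )
        result.rewiring = rew
        summary["rewire_p_C"] = rew.p_C
        summary["rewire_p_Q"] = rew.p_Q
        summary["observed_C"] = rew.observed_C

    # -- enrichment battery -------------------------------------------
    net_genes = gene_net.nodes
    part_labels = {g: c for g, c in partition.labels.items()}

    expr_corr = enrichment.correlation_matrix(bundle.expression)
    tissue_corr = enrichment.correlation_matrix(bundle.tissue)
    phylo_corr = enrichment.correlation_matrix(bundle.phylo)
    for name, mat in [
        ("expression", expr_corr), ("tissue", tissue_corr), ("phylo", phylo_corr)
    ]:
        res = enrichment.metric_enrichment(
            part_labels, mat, metric=name, n_boot=params.n_boot,
            seed=_seed_for(params.seed, f"enrich_{name}"),
        )
        result.enrichments[name] = res
        summary[f"enrich_p_{name}"] = res.p_value

    ppi_pairs = {
        frozenset((a, b)) for a, b, ev in bundle.ppi
        if ev in enrichment.BIOGRID_PHYSICAL_SYSTEMS and a != b
    }
    res = enrichment.ppi_count_enrichment(
        part_labels, ppi_pairs, n_boot=params.n_boot,
        seed=_seed_for(params.seed, "enrich_ppi"),
    )
    result.enrichments["ppi"] = res
    summary["enrich_p_ppi"] = res.p_value

    branches = {
        b: (gb.annotations, gb.dag, gb.level) for b, gb in bundle.go.items()
    }
    go_res = enrichment.go_similarity_d(
        part_labels, branches, n_boot=params.n_boot,
        seed=_seed_for(params.seed, "enrich_go"),
    )
    for b, res in go_res.items():
        result.enrichments[f"go_{b}"] = res
        summary[f"enrich_p_go_{b}"] = res.p_value

    hub_nodes = communities.hubs(gene_net, params.hub_percentile)
    go_pairs = [
        (r.gene_id, r.term_id)
        for gb in bundle.go.values()
        for r in gb.annotations.records
    ]
    if hub_nodes:
        result.hub_table = enrichment.hub_go_fisher(
            hub_nodes, set(net_genes) | hub_nodes, go_pairs,
            correction=params.correction,
        )
        summary["n_hubs"] = float(len(hub_nodes))

    cont = enrichment.level1_sharing_chisq(part_labels, B1)
    result.contingency = cont
    summary["level1_chi_sq"] = cont.chi_sq
    summary["level1_chi_p"] = cont.p
    summary["frac_same_within"] = cont.frac_same_within
    summary["frac_same_overall"] = cont.frac_same_overall

    assignments, matrix = community_mapping.assign_communities_to_groups(
        part_labels, B1
    )
    result.group_assignments = assignments
    result.group_matrix = matrix
    best = [a for a in assignments if a.p <= 1e-4]
    summary["n_significant_group_assignments"] = float(len(best))

    if params.run_phenotype_clustering and len(B1.col_ids) >= 3:
        dend = bootstrap_support(
            B1, n_boot=params.phen_n_boot,
            seed=_seed_for(params.seed, "phen_boot"),
        )
        result.dendrogram = dend
        nontrivial = dend.support[
            dend.support["cluster"].apply(len) < len(dend.leaves)
        ]
        if len(nontrivial):
            summary["mean_cluster_au"] = float(nontrivial["au"].mean())
            summary["mean_cluster_bp"] = float(nontrivial["bp"].mean())

    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.B.write_tsv(out / "biadjacency.tsv")
    result.B1.write_tsv(out / "biadjacency_level1.tsv")
    result.gene_assoc.write_tsv(out / "gene_association.tsv")
    result.gene_net.write_tsv(out / "gene_network.tsv")
    result.gene_net.write_graphml(out / "gene_network.graphml")
    result.partition.write_tsv(out / "gene_communities.tsv")
    result.profile.write_tsv(out / "degree_profile.tsv")
    if result.phen_net is not None:
        result.phen_net.write_tsv(out / "phenotype_network.tsv")
        if result.phen_partition is not None:
            result.phen_partition.write_tsv(out / "phenotype_communities.tsv")
    if result.rewiring is not None:
        result.rewiring.write_tsv(out / "rewiring_null.tsv")
    if result.group_matrix is not None:
        result.group_matrix.write_tsv(out / "community_group_neglogp.tsv")
    if result.hub_table is not None:
        result.hub_table.to_csv(out / "hub_go_enrichment.tsv", sep="\t", index=False)
    if result.dendrogram is not None:
        result.dendrogram.write_newick(out / "phenotype_clusters.nwk")
        result.dendrogram.write_merge_tsv(out / "phenotype_clusters_merges.tsv")
    summary = {k: (None if isinstance(v, float) and np.isnan(v) else v)
               for k, v in sorted(result.summary.items())}
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=False,
                   default=float) + "\n",
        encoding="utf-8",
    )
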