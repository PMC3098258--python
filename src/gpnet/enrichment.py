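"""Functional enrichment of gene communities against resampled controls.

Each enrichment compares the values a pairwise metric takes on
within-community gene pairs against a control built by drawing random
pseudo-communities of the same sizes from the network's gene universe
(without replacement within a pseudo-community, independently across
replicates).  Expression, tissue and phylogenetic-profile similarity use
Pearson correlation matrices; GO similarity reuses the association
module's full d pipeline on each GO branch; protein-protein interaction
enrichment compares the observed within-community interaction count with
the null count distribution via an empirical tail p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .association import fdr_correct, pairwise_association
from .biadjacency import WeightedBiadjacency, build_biadjacency
from .communities import Partition

__all__ = [
    "CommunityEnrichmentResult",
    "ContingencyResult",
    "correlation_matrix",
    "within_community_values",
    "resampled_control",
    "compare_distributions",
    "metric_enrichment",
    "ppi_count_enrichment",
    "go_similarity_d",
    "hub_go_fisher",
    "level1_sharing_chisq",
    "load_ppi",
    "BIOGRID_PHYSICAL_SYSTEMS",
]

#: Experimental evidence types accepted as physical interactions.
BIOGRID_PHYSICAL_SYSTEMS = (
    "Affinity Capture-MS",
    "Affinity Capture-RNA",
    "Affinity Capture-Western",
    "Co-fractionation",
    "Co-localization",
    "Co-purification",
    "FRET",
    "Two-Hybrid",
    "Biochemical Activity",
    "Co-crystal Structure",
    "Far Western",
    "Protein-peptide",
    "Protein-RNA",
    "Reconstituted Complex",
)


@dataclass
class CommunityEnrichmentResult:
    metric: str
    within_values: np.ndarray
    control_values: np.ndarray
    p_value: float
    n_boot: int
    seed: int
    extra: Dict[str, float] = field(default_factory=dict)

    @property
    def within_mean(self) -> float:
        return float(np.mean(self.within_values)) if len(self.within_values) else float("nan")

    @property
    def control_mean(self) -> float:
        return float(np.mean(self.control_values)) if len(self.control_values) else float("nan")


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi_sq: float
    dof: int
    p: float
    frac_same_within: float
    frac_same_overall: float


# ---------------------------------------------------------------------------
# pairwise-metric machinery


def correlation_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between the rows of a genes x features table."""
    vals = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals)
    return pd.DataFrame(corr, index=df.index, columns=df.index)


def _pair_values(matrix: pd.DataFrame, members: Sequence[str]) -> np.ndarray:
    sub = matrix.loc[list(members), list(members)].to_numpy()
    iu, ju = np.triu_indices(len(members), k=1)
    return sub[iu, ju]


def within_community_values(partition, matrix: pd.DataFrame) -> np.ndarray:
    """Pooled metric values for all unordered within-community pairs.

    Genes missing from the matrix are skipped (with a warning counter);
    size-1 communities contribute nothing.
    """
    labels = partition.labels if isinstance(partition, Partition) else partition
    avail = set(matrix.index)
    missing = {g for g in labels if g not in avail}
    if missing:
        warnings.warn(f"{len(missing)} partition genes missing from metric matrix")
    groups: Dict[int, List[str]] = {}
    for g, c in labels.items():
        if g in avail:
            groups.setdefault(c, []).append(g)
    chunks = [
        _pair_values(matrix, sorted(members))
        for members in groups.values()
        if len(members) >= 2
    ]
    out = np.concatenate(chunks) if chunks else np.array([])
    # undefined metric values (e.g. correlation of a constant profile)
    return out[np.isfinite(out)]


def resampled_control(
    sizes: Sequence[int],
    universe: Sequence[str],
    matrix: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null within-pair values from random same-size pseudo-communities.

    Each replicate draws one pseudo-community per size, without
    replacement within a community, from ``universe``; within-pair values
    are pooled across replicates.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(set(universe) & set(matrix.index))
    n_univ = len(universe)
    sizes = [s for s in sizes if s >= 2]
    chunks = []
    uni = np.array(universe)
    vals = matrix.loc[universe, universe].to_numpy()
    for _ in range(n_boot):
        for s in sizes:
            pick = rng.choice(n_univ, size=min(s, n_univ), replace=False)
            sub = vals[np.ix_(pick, pick)]
            iu, ju = np.triu_indices(len(pick), k=1)
            chunks.append(sub[iu, ju])
    out = np.concatenate(chunks) if chunks else np.array([])
    return out[np.isfinite(out)]


def compare_distributions(within: np.ndarray, control: np.ndarray) -> float:
    """One-sided (within > control) two-sample Wilcoxon p-value."""
    if len(within) == 0 or len(control) == 0:
        raise ValueError("both vectors must be non-empty")
    return float(
        stats.mannwhitneyu(
            within, control, alternative="greater", method="asymptotic"
        ).pvalue
    )


def metric_enrichment(
    partition,
    matrix: pd.DataFrame,
    metric: str = "expr_corr",
    n_boot: int = 1000,
    seed: int = 0,
    universe: Optional[Iterable[str]] = None,
) -> CommunityEnrichmentResult:
    """Within-vs-control enrichment for any symmetric pairwise metric."""
    labels = partition.labels if isinstance(partition, Partition) else partition
    if universe is None:
        universe = [g for g in labels if g in set(matrix.index)]
    groups: Dict[int, int] = {}
    for g, c in labels.items():
        if g in set(matrix.index):
            groups[c] = groups.get(c, 0) + 1
    sizes = [s for s in groups.values() if s >= 2]
    within = within_community_values(labels, matrix)
    control = resampled_control(sizes, universe, matrix, n_boot=n_boot, seed=seed)
    p = compare_distributions(within, control)
    return CommunityEnrichmentResult(
        metric=metric, within_values=within, control_values=control,
        p_value=p, n_boot=n_boot, seed=seed,
    )


# ---------------------------------------------------------------------------
# protein-protein interactions


def load_ppi(
    path,
    keep_systems: Sequence[str] = BIOGRID_PHYSICAL_SYSTEMS,
    sep: str = "\t",
    comment: str = "#",
) -> Set[frozenset]:
    """Read a PPI pair list, keeping physical-evidence interactions.

    Expects columns gene_a, gene_b and optionally an experimental-system
    column; rows whose system is absent from ``keep_systems`` (e.g.
    genetic evidence such as "Dosage Rescue") are dropped.  Self
    interactions are discarded.
    """
    keep = set(keep_systems)
    pairs: Set[frozenset] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or (comment and line.startswith(comment)):
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                continue
            a, b = parts[0].strip(), parts[1].strip()
            if len(parts) >= 3 and parts[2].strip() and parts[2].strip() not in keep:
                continue
            if a and b and a != b:
                pairs.add(frozenset((a, b)))
    return pairs


def _count_within(pairs_by_gene: Dict[str, Set[str]], groups: List[List[str]]) -> int:
    count = 0
    for members in groups:
        mset = set(members)
        for g in members:
            partners = pairs_by_gene.get(g)
            if partners:
                count += len(partners & mset)
    return count // 2


def ppi_count_enrichment(
    partition,
    ppi_pairs: Iterable[frozenset],
    n_boot: int = 1000,
    seed: int = 0,
    universe: Optional[Iterable[str]] = None,
) -> CommunityEnrichmentResult:
    """Observed within-community interaction count vs resampled nulls.

    The control pools, per replicate, the interaction count over random
    same-size pseudo-communities; the reported p is the empirical tail
    fraction #{null >= observed} / n_boot (0 when the observed count
    exceeds every null replicate), the same convention as the rewiring
    null.
    """
    labels = partition.labels if isinstance(partition, Partition) else partition
    pairs_by_gene: Dict[str, Set[str]] = {}
    for pr in ppi_pairs:
        a, b = tuple(pr)
        pairs_by_gene.setdefault(a, set()).add(b)
        pairs_by_gene.setdefault(b, set()).add(a)
    if universe is None:
        universe = sorted(labels)
    universe = sorted(set(universe))
    if not (set(universe) & set(pairs_by_gene)):
        warnings.warn("no PPI overlap with network genes; p undefined")
        return CommunityEnrichmentResult(
            metric="ppi_count", within_values=np.array([0.0]),
            control_values=np.array([]), p_value=float("nan"),
            n_boot=n_boot, seed=seed,
        )
    groups: Dict[int, List[str]] = {}
    for g, c in labels.items():
        groups.setdefault(c, []).append(g)
    members = [sorted(m) for m in groups.values() if len(m) >= 2]
    observed = _count_within(pairs_by_gene, members)
    rng = np.random.default_rng(seed)
    uni = np.array(universe)
    null_counts = np.empty(n_boot)
    for r in range(n_boot):
        pseudo = [
            list(uni[rng.choice(len(uni), size=min(len(m), len(uni)), replace=False)])
            for m in members
        ]
        null_counts[r] = _count_within(pairs_by_gene, pseudo)
    p = float((null_counts >= observed).mean())
    return CommunityEnrichmentResult(
        metric="ppi_count", within_values=np.array([float(observed)]),
        control_values=null_counts, p_value=p, n_boot=n_boot, seed=seed,
        extra={"observed_count": float(observed)},
    )


# ---------------------------------------------------------------------------
# GO similarity


def go_similarity_d(
    partition,
    branches: Dict[str, tuple],
    n_boot: int = 1000,
    seed: int = 0,
    correction: str = "bh",
) -> Dict[str, CommunityEnrichmentResult]:
    """Per-branch enrichment of the GO-based d score within communities.

    ``branches`` maps a branch name (e.g. "BP") to (annotations, dag,
    level); the association module's full d pipeline runs on the branch's
    biadjacency matrix, then the within-vs-control comparison is applied
    to the resulting gene x gene d matrix.  Branches with no usable
    annotations are skipped.
    """
    labels = partition.labels if isinstance(partition, Partition) else partition
    results: Dict[str, CommunityEnrichmentResult] = {}
    for i, (branch, (annots, dag, level)) in enumerate(sorted(branches.items())):
        try:
            B = build_biadjacency(annots, dag, level)
        except ValueError as exc:  # includes OntologyError
            warnings.warn(f"GO branch {branch} skipped: {exc}")
            continue
        A = pairwise_association(B, correction=correction)
        dmat = A.to_frame()
        res = metric_enrichment(
            labels, dmat, metric=f"go_d_{branch}", n_boot=n_boot, seed=seed + i
        )
        results[branch] = res
    return results


# ---------------------------------------------------------------------------
# hub GO over-representation


def hub_go_fisher(
    hub_genes: Iterable[str],
    universe: Iterable[str],
    go_annotations: Iterable[Tuple[str, str]],
    correction: str = "bh",
) -> pd.DataFrame:
    """One-tailed Fisher over-representation of GO terms among hubs.

    For every term annotated to >=1 universe gene the 2x2 table
    (hub / non-hub) x (has term / lacks term) is tested with the
    one-tailed (greater) Fisher exact test; q-values use the same
    correction backend as the association module.
    """
    hub_set = set(hub_genes)
    uni = set(universe)
    if not hub_set <= uni:
        raise ValueError("universe must contain all hubs")
    genes_by_term: Dict[str, Set[str]] = {}
    for gene, term in go_annotations:
        if gene in uni:
            genes_by_term.setdefault(term, set()).add(gene)
    rows = []
    n_hub = len(hub_set)
    n_other = len(uni) - n_hub
    for term in sorted(genes_by_term):
        with_term = genes_by_term[term]
        a = len(with_term & hub_set)
        b = n_hub - a
        c = len(with_term) - a
        d = n_other - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term, a, len(with_term), odds, p))
    if not rows:
        return pd.DataFrame(columns=["term", "n_hub", "n_total", "odds_ratio", "p", "q"])
    df = pd.DataFrame(rows, columns=["term", "n_hub", "n_total", "odds_ratio", "p"])
    df["q"] = fdr_correct(df["p"].to_numpy(), method=correction)
    return df.sort_values(["p", "term"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# level-1 term sharing


def level1_sharing_chisq(
    partition,
    B_level1: WeightedBiadjacency,
    bins: Sequence[int] = (0, 1, 2),
) -> ContingencyResult:
    """Chi-square for level-1 term sharing within communities vs overall.

    For every unordered gene pair the number of shared level-1 terms
    (both entries positive) is binned as {0, 1, 2, >=3}; the 2 x 4
    independence table of within-community pairs against all pairs has 3
    degrees of freedom.  Also reports the fraction of pairs sharing at
    least one term, within communities and overall.
    """
    labels = partition.labels if isinstance(partition, Partition) else partition
    if not labels:
        raise ValueError("no communities supplied")
    genes = [g for g in B_level1.row_ids if g in labels]
    if len(genes) < 2:
        raise ValueError("fewer than 2 partition genes present in B")
    gi = [B_level1.row_ids.index(g) for g in genes]
    X = (B_level1.values[gi] > 0).astype(int)
    shared = X @ X.T
    lab = np.array([labels[g] for g in genes])
    iu, ju = np.triu_indices(len(genes), k=1)
    counts = shared[iu, ju]
    same = lab[iu] == lab[ju]

    edges = list(bins) + [np.inf]
    def _bin(v: np.ndarray) -> np.ndarray:
        out = np.zeros(len(edges), dtype=int)
        for i, e in enumerate(edges[:-1]):
            out[i] = int((v == e).sum()) if np.isfinite(e) else 0
        out[-1] = int((v > edges[-2]).sum())
        return out

    within_bins = _bin(counts[same])
    all_bins = _bin(counts)
    table = np.vstack([within_bins, all_bins])
    # drop all-zero columns (chi-square undefined there)
    keep = table.sum(axis=0) > 0
    table_used = table[:, keep]
    if table_used.shape[1] < 2 or (counts[same].size == 0):
        chi, p, dof = 0.0, 1.0, 0
    else:
        chi, p, dof, _ = stats.chi2_contingency(table_used, correction=False)
    frac_within = float((counts[same] >= 1).mean()) if same.any() else float("nan")
    frac_all = float((counts >= 1).mean())
    return ContingencyResult(
        table=table, chi_sq=float(chi), dof=int(dof), p=float(p),
        frac_same_within=frac_within, frac_same_overall=frac_all,
    )
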