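"""Hierarchical clustering of high-level phenotypes with bootstrap support.

Level-1 phenotype terms are clustered by the genes they share: the
distance between two term columns of the gene x term biadjacency matrix
is 1 - Pearson correlation, merged by average linkage.  Cluster
uncertainty is assessed by multiscale bootstrap: rows (genes) are
resampled at several scales r (resample size round(r * n)), the plain
bootstrap proportion BP_r of each observed cluster is recorded per
scale, and the approximately unbiased (AU) support extrapolates the
normal-theory z-values across scales,

    qnorm(1 - BP_r) ~= v * sqrt(r) + c / sqrt(r)   (weighted LS)

giving AU = Phi(c - v) and a smoothed BP = Phi(-(v + c)) at r = 1.
Clusters reproduced in every replicate at every scale have AU = BP = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .biadjacency import WeightedBiadjacency

__all__ = ["Dendrogram", "cluster_level1", "bootstrap_support", "correlation_distance"]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


def correlation_distance(columns: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between matrix columns.

    Zero-variance columns have undefined correlation; their distances
    are set to 1 with a warning.
    """
    X = np.asarray(columns, dtype=float)
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant columns: correlation undefined, "
            "distance set to 1"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    D = 1.0 - corr
    D[np.isnan(D)] = 1.0
    np.fill_diagonal(D, 0.0)
    # guard tiny negative values from float error
    return np.maximum(D, 0.0)


def _linkage(columns: np.ndarray) -> np.ndarray:
    D = correlation_distance(columns)
    return hierarchy.linkage(squareform(D, checks=False), method="average")


def _cluster_sets(Z: np.ndarray, n_leaves: int) -> List[FrozenSet[int]]:
    """Leaf sets of every internal node of a linkage tree."""
    sets: Dict[int, FrozenSet[int]] = {i: frozenset([i]) for i in range(n_leaves)}
    out: List[FrozenSet[int]] = []
    for i, (a, b, _, _) in enumerate(Z):
        merged = sets[int(a)] | sets[int(b)]
        sets[n_leaves + i] = merged
        out.append(merged)
    return out


@dataclass
class Dendrogram:
    """Average-linkage merge tree over term columns with optional support."""

    linkage: np.ndarray
    leaves: List[str]
    support: Optional[pd.DataFrame] = None  # cluster, bp, au, n_boot
    n_boot: int = 0
    seed: Optional[int] = None

    def cluster_sets(self) -> List[FrozenSet[str]]:
        return [
            frozenset(self.leaves[i] for i in s)
            for s in _cluster_sets(self.linkage, len(self.leaves))
        ]

    def cophenetic_matrix(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.leaves, columns=self.leaves)

    def support_for(self, members: FrozenSet[str]) -> Optional[pd.Series]:
        if self.support is None:
            return None
        key = tuple(sorted(members))
        hit = self.support[self.support["cluster"] == key]
        return hit.iloc[0] if len(hit) else None

    def to_newick(self) -> str:
        """Newick string; internal node labels carry AU support when present."""
        n = len(self.leaves)
        sets = _cluster_sets(self.linkage, n)
        au_by_set: Dict[Tuple[str, ...], float] = {}
        if self.support is not None:
            for _, row in self.support.iterrows():
                au_by_set[row["cluster"]] = row["au"]

        def label(node: int) -> str:
            if node < n:
                return self.leaves[node]
            a, b, h, _ = self.linkage[node - n]
            members = tuple(sorted(self.leaves[i] for i in sets[node - n]))
            au = au_by_set.get(members)
            tag = f"{au:.3f}" if au is not None else ""
            return f"({label(int(a))}:{h/2:.6g},{label(int(b))}:{h/2:.6g}){tag}"

        return label(2 * n - 2) + ";"

    def write_newick(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")

    def write_merge_tsv(self, path) -> None:
        df = pd.DataFrame(self.linkage, columns=["child_a", "child_b", "height", "size"])
        df.to_csv(path, sep="\t", index=False)


def cluster_level1(B: WeightedBiadjacency) -> Dendrogram:
    """Cluster the term columns of a (level-1) biadjacency matrix."""
    if len(B.col_ids) < 3:
        raise ValueError("need at least 3 columns to cluster")
    Z = _linkage(B.values)
    return Dendrogram(linkage=Z, leaves=list(B.col_ids))


def _au_from_scales(
    bp: np.ndarray, scales: np.ndarray, n_per_scale: np.ndarray
) -> Tuple[float, float]:
    """(au, bp_smoothed) from per-scale bootstrap proportions.

    Falls back to the plain r=1-nearest BP when the cluster shows no
    usable cross-scale variation (all 0, all 1, or < 2 interior scales).
    """
    plain = float(bp[np.argmin(np.abs(scales - 1.0))])
    usable = (bp > 0.0) & (bp < 1.0)
    if usable.sum() < 2 or np.allclose(bp[usable], bp[usable][0]):
        return plain, plain
    r = scales[usable]
    z = stats.norm.ppf(1.0 - bp[usable])
    # delta-method weights: var(z) = bp(1-bp) / (n * phi(z)^2)
    w = (stats.norm.pdf(z) ** 2) * n_per_scale[usable] / (bp[usable] * (1 - bp[usable]))
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    WX = X * w[:, None]
    try:
        coef = np.linalg.solve(X.T @ WX, WX.T @ z)
    except np.linalg.LinAlgError:
        return plain, plain
    v, c = coef
    au = float(stats.norm.cdf(c - v))
    bp_s = float(stats.norm.cdf(-(v + c)))
    return au, bp_s


def bootstrap_support(
    B: WeightedBiadjacency,
    n_boot: int = 10000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
) -> Dendrogram:
    """Multiscale bootstrap support for the observed clusters.

    ``n_boot`` replicates are split evenly across the resampling scales;
    each replicate resamples rows (genes) with replacement at size
    round(scale * n_rows), reclusters, and records which observed
    clusters reappear.  Scales yielding < 3 rows are skipped.  The
    reported ``bp`` is the plain proportion at scale 1; ``au`` the
    multiscale extrapolation.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    dend = cluster_level1(B)
    n_rows = B.values.shape[0]
    observed = dend.cluster_sets()
    obs_idx = [frozenset(B.col_ids.index(t) for t in s) for s in observed]
    # the root cluster is present in every replicate by definition
    scales_arr = np.array([s for s in scales if round(s * n_rows) >= 3], dtype=float)
    if scales_arr.size == 0:
        raise ValueError("no usable scales for this matrix")
    reps_per_scale = max(1, n_boot // len(scales_arr))
    rng = np.random.default_rng(seed)
    hits = np.zeros((len(observed), len(scales_arr)))
    for si, r in enumerate(scales_arr):
        size = int(round(r * n_rows))
        for _ in range(reps_per_scale):
            rows = rng.integers(0, n_rows, size=size)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Z = _linkage(B.values[rows])
            found = set(_cluster_sets(Z, len(B.col_ids)))
            for ci, s in enumerate(obs_idx):
                if s in found:
                    hits[ci, si] += 1
    bp = hits / reps_per_scale
    n_per_scale = np.full(len(scales_arr), reps_per_scale, dtype=float)
    rows_out = []
    for ci, s in enumerate(observed):
        members = tuple(sorted(s))
        if len(s) == len(B.col_ids):
            au = bp1 = 1.0  # root cluster: support 1 by definition
        else:
            au, _ = _au_from_scales(bp[ci], scales_arr, n_per_scale)
            bp1 = float(bp[ci][np.argmin(np.abs(scales_arr - 1.0))])
        rows_out.append((members, bp1, au))
    support = pd.DataFrame(rows_out, columns=["cluster", "bp", "au"])
    support["n_boot"] = reps_per_scale * len(scales_arr)
    return Dendrogram(
        linkage=dend.linkage, leaves=dend.leaves, support=support,
        n_boot=n_boot, seed=seed,
    )
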