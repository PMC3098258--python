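"""Pairwise association scores (d) for genes or phenotypes.

For a pair of genes (i1, i2) and a level-L phenotype column j, the two
granularity-weight vectors of the genes over the dataset-annotated
descendant-or-self terms of j are compared with a two-sided two-sample
Wilcoxon rank-sum test; a large p-value means the two annotation
profiles under j are indistinguishable (similar).  The p-values are
FDR-corrected (Benjamini-Hochberg by default) pooled across all
pair x phenotype tests, and d_{i1i2} is the mean of the corrected values
over *all* level-L columns, with columns conveying no signal for the
pair contributing 0.  By default a column carries signal for a pair only
when BOTH genes are annotated under it, which makes d exactly 0 for
pairs sharing no level-L phenotype.

The phenotype-phenotype network is the same pipeline applied to the
transposed biadjacency matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .biadjacency import WeightedBiadjacency

__all__ = [
    "AssociationMatrix",
    "NetworkEdgeList",
    "wilcoxon_rank_sum_p",
    "pair_phenotype_score",
    "aggregate_d",
    "fdr_correct",
    "pairwise_association",
    "build_network",
    "suggest_cutoff",
    "DEFAULT_CUTOFFS",
]

#: Shipped default edge-weight cutoffs: (kind, level) -> d_cutoff.
DEFAULT_CUTOFFS = {
    ("gene", 5): 0.009,
    ("gene", 8): 0.011,
    ("phenotype", 5): 0.005,
    ("phenotype", 8): 0.002,
}


# ---------------------------------------------------------------------------
# rank-sum p-value


def wilcoxon_rank_sum_p(u, v, exact_max_n: int = 10) -> float:
    """Two-sided two-sample Wilcoxon rank-sum p-value.

    Exact null for small tie-free samples (both sides <= ``exact_max_n``);
    otherwise the normal approximation with tie correction and continuity
    correction, mirroring R's wilcox.test fallback behaviour.  Fully
    degenerate comparisons (every value identical) return 1.0.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    n1, n2 = len(u), len(v)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    comb = np.concatenate([u, v])
    if np.all(comb == comb[0]):
        return 1.0  # exact-tie convention
    uniq, counts = np.unique(comb, return_counts=True)
    has_ties = len(uniq) < n1 + n2
    if not has_ties and max(n1, n2) <= exact_max_n:
        return float(
            stats.mannwhitneyu(u, v, alternative="two-sided", method="exact").pvalue
        )
    ranks = stats.rankdata(comb)
    r1 = ranks[:n1].sum()
    ustat = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie_term = float(((counts**3) - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(ustat - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# containers


@dataclass
class AssociationMatrix:
    """Symmetric matrix of d scores in [0, 1] with a zero diagonal."""

    ids: List[str]
    values: np.ndarray
    level: int
    kind: str = "gene"  # gene | phenotype
    per_phenotype_store: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("association matrix must be square over ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("association matrix must be symmetric")
        np.fill_diagonal(self.values, 0.0)
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("d scores must lie in [0, 1]")
        self._index = {g: i for i, g in enumerate(self.ids)}

    def d(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


@dataclass
class NetworkEdgeList:
    """Undirected weighted edge list retained at a d cutoff.

    Edges are stored canonically (a < b) and sorted; isolated nodes are
    absent by construction.
    """

    edges: List[Tuple[str, str, float]]
    d_cutoff: float
    kind: str = "gene"
    level: int = 0

    def __post_init__(self):
        canon = []
        for a, b, w in self.edges:
            if a == b:
                continue
            if b < a:
                a, b = b, a
            canon.append((a, b, float(w)))
        self.edges = sorted(canon)

    @property
    def nodes(self) -> List[str]:
        out = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return sorted(out)

    def to_graph(self, weighted: bool = True):
        import networkx as nx

        g = nx.Graph()
        for a, b, w in self.edges:
            if weighted:
                g.add_edge(a, b, weight=w)
            else:
                g.add_edge(a, b)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["node_a", "node_b", "d"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), str(path))

    @classmethod
    def read_tsv(cls, path, d_cutoff: float = 0.0, kind: str = "gene", level: int = 0):
        df = pd.read_csv(path, sep="\t")
        edges = [
            (str(a), str(b), float(w))
            for a, b, w in df.itertuples(index=False, name=None)
        ]
        return cls(edges=edges, d_cutoff=d_cutoff, kind=kind, level=level)


# ---------------------------------------------------------------------------
# column profiles


def _column_profiles(B: WeightedBiadjacency):
    """Per-column weight matrices.

    For each column j yields (row_ids_under_j, W) where W[r, t] is the
    granularity weight of support term t for row r (0 when the row lacks
    that term).  The support axis is the union, over all rows, of the
    contributing annotated terms of j.
    """
    if B.cells is None:
        raise ValueError(
            "biadjacency lacks per-cell contribution detail; "
            "build it with build_biadjacency()"
        )
    by_col: Dict[str, Dict[str, Dict[str, float]]] = {}
    for (row, col), contrib in B.cells.items():
        by_col.setdefault(col, {})[row] = contrib
    profiles = {}
    for col in B.col_ids:
        rows = by_col.get(col)
        if not rows:
            continue
        support = sorted({t for contrib in rows.values() for t in contrib})
        sidx = {t: k for k, t in enumerate(support)}
        row_ids = sorted(rows)
        W = np.zeros((len(row_ids), len(support)))
        for r, rid in enumerate(row_ids):
            for t, w in rows[rid].items():
                W[r, sidx[t]] = w
        profiles[col] = (row_ids, W)
    return profiles


def pair_phenotype_score(
    B: WeightedBiadjacency,
    i1: str,
    i2: str,
    j: str,
    gate: str = "shared",
    exact_max_n: int = 10,
) -> Optional[float]:
    """Raw (uncorrected) per-phenotype similarity p for one pair.

    Returns ``None`` (the no-signal sentinel) when the column conveys no
    signal for the pair under the chosen gate: with ``gate="shared"``
    (default) signal requires both rows annotated under j; with
    ``gate="either"`` one annotated row suffices.
    """
    if i1 == i2:
        raise ValueError("pair must consist of two distinct rows")
    profiles = _column_profiles(B)
    if j not in profiles:
        return None
    row_ids, W = profiles[j]
    idx = {r: k for k, r in enumerate(row_ids)}
    m = W.shape[1]
    u = W[idx[i1]] if i1 in idx else np.zeros(m)
    v = W[idx[i2]] if i2 in idx else np.zeros(m)
    if gate == "shared":
        if i1 not in idx or i2 not in idx:
            return None
    elif gate == "either":
        if i1 not in idx and i2 not in idx:
            return None
    else:
        raise ValueError(f"unknown gate {gate!r}")
    return wilcoxon_rank_sum_p(u, v, exact_max_n=exact_max_n)


# ---------------------------------------------------------------------------
# FDR correction


def fdr_correct(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Corrected q-values for a pooled collection of p-values.

    "bh" (default) is Benjamini-Hochberg; "by" the Benjamini-Yekutieli
    variant for dependent tests.  q-values are monotone in p and >= p.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    methods = {"bh": "fdr_bh", "by": "fdr_by"}
    if method not in methods:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=methods[method])[1]


def aggregate_d(q_signal: Sequence[float], n_columns: int) -> float:
    """Final pair score: mean corrected similarity over ALL level-L columns.

    ``q_signal`` holds the corrected values of the signal columns only;
    the remaining (no-signal) columns contribute 0, so
    d = sum(q_signal) / n_columns, which lies in [0, 1].
    """
    if n_columns <= 0:
        raise ValueError("n_columns must be positive")
    q = np.asarray(list(q_signal), dtype=float)
    if q.size and (q.min() < 0 or q.max() > 1):
        raise ValueError("corrected values must lie in [0, 1]")
    if len(q) > n_columns:
        raise ValueError("more signal columns than columns")
    return float(q.sum() / n_columns)


# ---------------------------------------------------------------------------
# full pairwise pipeline


def pairwise_association(
    B: WeightedBiadjacency,
    correction: str = "bh",
    gate: str = "shared",
    exact_max_n: int = 10,
    store_per_phenotype: bool = False,
) -> AssociationMatrix:
    """Compute the full symmetric d matrix over the rows of ``B``.

    Enumeration is restricted to pairs sharing at least one column
    (other pairs are d = 0 by construction under the default gate).
    Identical rank-sum configurations are cached: the two-sided p depends
    only on the two value multisets, so pairs with matching sorted weight
    vectors share one test.
    """
    profiles = _column_profiles(B)
    ids = list(B.row_ids)
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    n_cols = len(B.col_ids)

    tests: List[Tuple[int, int, str]] = []  # (row_a, row_b, column)
    pvals: List[float] = []
    cache: Dict[Tuple[bytes, bytes], float] = {}

    def cached_p(u: np.ndarray, v: np.ndarray) -> float:
        ku = np.sort(u).tobytes()
        kv = np.sort(v).tobytes()
        key = (ku, kv) if ku <= kv else (kv, ku)
        hit = cache.get(key)
        if hit is None:
            hit = wilcoxon_rank_sum_p(u, v, exact_max_n=exact_max_n)
            cache[key] = hit
        return hit

    for col, (row_ids, W) in profiles.items():
        ridx = [index[r] for r in row_ids]
        k = len(row_ids)
        for a in range(k):
            ua = W[a]
            for b in range(a + 1, k):
                p = cached_p(ua, W[b])
                tests.append((ridx[a], ridx[b], col))
                pvals.append(p)
        if gate == "either":
            # one annotated row vs an all-zero profile: identical p for
            # every unannotated partner, computed once per annotated row
            zeros = np.zeros(W.shape[1])
            others = [i for g, i in index.items() if g not in set(row_ids)]
            for a in range(k):
                p = cached_p(W[a], zeros)
                for ob in others:
                    tests.append((min(ridx[a], ob), max(ridx[a], ob), col))
                    pvals.append(p)

    values = np.zeros((n, n))
    store_rows = []
    if tests:
        q = fdr_correct(pvals, method=correction)
        for (a, b, col), qv in zip(tests, q):
            values[a, b] += qv
            values[b, a] += qv
            if store_per_phenotype:
                store_rows.append((ids[a], ids[b], col, qv))
        values /= n_cols

    store = None
    if store_per_phenotype:
        store = pd.DataFrame(store_rows, columns=["id_a", "id_b", "column", "q"])
    kind = "gene" if B.axis_kind == "gene" else "phenotype"
    return AssociationMatrix(
        ids=ids, values=values, level=B.level, kind=kind, per_phenotype_store=store
    )


# ---------------------------------------------------------------------------
# thresholding


def build_network(A: AssociationMatrix, d_cutoff: float) -> NetworkEdgeList:
    """Retain edges with d >= d_cutoff; isolated nodes drop out."""
    if not 0.0 <= d_cutoff <= 1.0:
        raise ValueError("d_cutoff must lie in [0, 1]")
    iu, ju = np.triu_indices(len(A.ids), k=1)
    w = A.values[iu, ju]
    keep = w >= d_cutoff if d_cutoff > 0 else w > 0
    edges = [
        (A.ids[i], A.ids[j], float(x))
        for i, j, x in zip(iu[keep], ju[keep], w[keep])
    ]
    if not edges:
        warnings.warn(f"cutoff {d_cutoff} retains zero edges")
    return NetworkEdgeList(edges=edges, d_cutoff=d_cutoff, kind=A.kind, level=A.level)


def suggest_cutoff(A: AssociationMatrix, quantile: float = 0.9) -> float:
    """Upper quantile of the nonzero d distribution.

    Automates the by-inspection choice of d_cutoff: the retained edges
    are the strongest (1 - quantile) fraction of nonzero associations.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly between 0 and 1")
    iu, ju = np.triu_indices(len(A.ids), k=1)
    w = A.values[iu, ju]
    nz = w[w > 0]
    if nz.size == 0:
        raise ValueError("association matrix has no nonzero entries")
    return float(np.quantile(nz, quantile))
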