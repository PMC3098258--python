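"""Mapping communities to level-1 phenotype groups and across networks.

Two independent uniform random subsets of sizes x and y drawn from an
N-element universe intersect in exactly z elements with probability
C(x, z) C(N-x, y-z) / C(N, y) (a hypergeometric law); the tail
P(Z >= z_obs) scores the observed community/group overlap, reported as
-log(p) for display.  Cross-network community comparison uses either
that tail probability or the symmetric overlap fraction
(z/x + z/y) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .biadjacency import WeightedBiadjacency
from .communities import Partition

__all__ = [
    "TIED",
    "UNASSIGNED",
    "GroupAssignment",
    "OverlapMatrix",
    "highest_scoring_level1",
    "intersection_pmf",
    "intersection_tail_p",
    "overlap_fraction",
    "assign_communities_to_groups",
    "cross_partition_matrix",
]

#: Sentinel: more than one equally high-scoring level-1 term.
TIED = "__tied__"
#: Sentinel: gene has an all-zero level-1 row.
UNASSIGNED = "__unassigned__"


def highest_scoring_level1(B_level1: WeightedBiadjacency, gene: str) -> str:
    """Argmax level-1 column of a gene's row, with tie/zero sentinels."""
    row = B_level1.row(gene)
    top = row.max()
    if top <= 0:
        return UNASSIGNED
    winners = [c for c, v in zip(B_level1.col_ids, row) if v == top]
    if len(winners) > 1:
        return TIED
    return winners[0]


def intersection_pmf(N: int, x: int, y: int, z: int) -> float:
    """P(|X ∩ Y| = z) for independent uniform subsets of sizes x, y.

    Zero for infeasible z (z > min(x, y) or y - z > N - x).
    """
    if x > N or y > N or min(N, x, y) < 0 or z < 0:
        raise ValueError("need 0 <= x, y <= N and z >= 0")
    if z > min(x, y) or y - z > N - x:
        return 0.0
    return float(stats.hypergeom.pmf(z, N, x, y))


def intersection_tail_p(N: int, x: int, y: int, z_obs: int) -> float:
    """P(Z >= z_obs): probability of an intersection at least as large."""
    if z_obs <= 0:
        return 1.0
    return float(stats.hypergeom.sf(z_obs - 1, N, x, y))


def overlap_fraction(set_a: Set, set_b: Set) -> float:
    """Mean containment fraction (z/x + z/y)/2; symmetric, in [0, 1]."""
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    z = len(set_a & set_b)
    return 0.5 * (z / len(set_a) + z / len(set_b))


@dataclass
class GroupAssignment:
    community: int
    group: str
    z: int
    x: int
    y: int
    N: int
    p: float

    @property
    def neg_log_p(self) -> float:
        return float(-np.log(self.p)) if self.p > 0 else float("inf")


@dataclass
class OverlapMatrix:
    rows: List
    cols: List
    values: np.ndarray
    mode: str  # "neg_log_p" or "fraction"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.cols)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="community")

    def clustered_row_order(self) -> List:
        """Row order from hierarchical clustering (Euclidean, average)."""
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist

        if len(self.rows) < 3:
            return list(self.rows)
        vals = np.nan_to_num(self.values, posinf=0.0)
        Z = hierarchy.linkage(pdist(vals), method="average")
        order = hierarchy.leaves_list(Z)
        return [self.rows[i] for i in order]


def assign_communities_to_groups(
    partition,
    B_level1: WeightedBiadjacency,
) -> Tuple[List[GroupAssignment], OverlapMatrix]:
    """Score every community against every level-1 phenotype group.

    Groups are the sets of genes whose unique highest-scoring level-1
    term is the group's term (tied or unassigned genes belong to no
    group).  The universe N is the set of genes both partitioned and
    present in the level-1 matrix.
    """
    labels = partition.labels if isinstance(partition, Partition) else partition
    avail = set(B_level1.row_ids)
    genes = sorted(set(labels) & avail)
    if not genes:
        raise ValueError("no partition genes present in the level-1 matrix")
    N = len(genes)
    groups: Dict[str, Set[str]] = {}
    for g in genes:
        top = highest_scoring_level1(B_level1, g)
        if top not in (TIED, UNASSIGNED):
            groups.setdefault(top, set()).add(g)
    comms: Dict[int, Set[str]] = {}
    for g in genes:
        comms.setdefault(labels[g], set()).add(g)

    assignments: List[GroupAssignment] = []
    comm_ids = sorted(comms)
    group_ids = sorted(groups)
    values = np.zeros((len(comm_ids), len(group_ids)))
    for i, c in enumerate(comm_ids):
        for j, grp in enumerate(group_ids):
            z = len(comms[c] & groups[grp])
            p = intersection_tail_p(N, len(comms[c]), len(groups[grp]), z)
            a = GroupAssignment(
                community=c, group=grp, z=z, x=len(comms[c]),
                y=len(groups[grp]), N=N, p=p,
            )
            assignments.append(a)
            values[i, j] = a.neg_log_p
    matrix = OverlapMatrix(rows=comm_ids, cols=group_ids, values=values, mode="neg_log_p")
    return assignments, matrix


def cross_partition_matrix(
    partition_a,
    partition_b,
    id_map: Optional[Dict[str, str]] = None,
    mode: str = "tail_p",
) -> OverlapMatrix:
    """All-against-all community overlap between two partitions.

    ``id_map`` translates partition_b node ids into partition_a's
    namespace (identity when None); nodes that fail to translate, or
    translate outside the shared universe, are excluded from community
    sizes and from N.  ``mode`` selects -log tail probabilities
    ("tail_p") or the symmetric overlap fraction ("fraction").
    """
    if mode not in ("tail_p", "fraction"):
        raise ValueError(f"unknown mode {mode!r}")
    la = partition_a.labels if isinstance(partition_a, Partition) else partition_a
    lb = partition_b.labels if isinstance(partition_b, Partition) else partition_b
    if id_map is None:
        translated = {n: n for n in lb}
    else:
        translated = {n: id_map[n] for n in lb if n in id_map}
    universe = set(la) & set(translated.values())
    if not universe:
        raise ValueError("empty translated overlap universe between partitions")
    comms_a: Dict[int, Set[str]] = {}
    for n, c in la.items():
        if n in universe:
            comms_a.setdefault(c, set()).add(n)
    comms_b: Dict[int, Set[str]] = {}
    for n, c in lb.items():
        t = translated.get(n)
        if t in universe:
            comms_b.setdefault(c, set()).add(t)
    rows = sorted(comms_a)
    cols = sorted(comms_b)
    N = len(universe)
    values = np.zeros((len(rows), len(cols)))
    for i, ca in enumerate(rows):
        for j, cb in enumerate(cols):
            z = len(comms_a[ca] & comms_b[cb])
            if mode == "fraction":
                values[i, j] = 0.5 * (z / len(comms_a[ca]) + z / len(comms_b[cb]))
            else:
                p = intersection_tail_p(N, len(comms_a[ca]), len(comms_b[cb]), z)
                values[i, j] = -np.log(p) if p > 0 else np.inf
    return OverlapMatrix(
        rows=rows, cols=cols, values=values,
        mode="fraction" if mode == "fraction" else "neg_log_p",
    )
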