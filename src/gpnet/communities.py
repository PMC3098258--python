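"""Community extraction by Newman's spectral (leading-eigenvector) method.

The modularity matrix of a graph with adjacency A, degrees k and 2m edge
endpoints is B = A - k k^T / 2m.  A group g is recursively bisected along
the sign pattern of the leading eigenvector of the generalized modularity
matrix B(g) (B restricted to g with row sums subtracted from the
diagonal); a split is accepted only when it increases Q, and an optional
Kernighan-Lin style single-node fine-tuning pass follows each spectral
division.  Detection runs on the binarized graph by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy import linalg

__all__ = ["Partition", "newman_spectral", "modularity", "hubs"]

_TOL = 1e-10


@dataclass
class Partition:
    """Community labels (node -> small integer) plus the achieved Q."""

    labels: Dict[str, int]
    Q: float
    method_meta: Dict[str, object] = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def communities(self) -> List[Set[str]]:
        out: Dict[int, Set[str]] = {}
        for node, c in self.labels.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]

    def sizes(self) -> List[int]:
        return [len(c) for c in self.communities()]

    def to_frame(self):
        import pandas as pd

        rows = sorted(self.labels.items())
        return pd.DataFrame(rows, columns=["node", "community"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path):
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        labels = {str(n): int(c) for n, c in df.itertuples(index=False, name=None)}
        return cls(labels=labels, Q=float("nan"))


def _as_graph(net, weighted: bool = False) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    return net.to_graph(weighted=weighted)


def _kl_refine(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style fine-tuning of a bisection vector.

    Repeatedly moves each node exactly once (greedily, even through
    negative gains), keeps the best prefix of moves, and iterates while
    the objective s^T B(g) s improves.
    """
    n = len(s)
    diag = np.diag(Bg).copy()
    s = s.copy()
    while True:
        y = Bg @ s
        q0 = float(s @ y)
        s_work = s.copy()
        moved = np.zeros(n, dtype=bool)
        order = np.empty(n, dtype=int)
        running = np.empty(n)
        cur = q0
        yw = y.copy()
        for step in range(n):
            delta = -4.0 * s_work * yw + 4.0 * diag
            delta[moved] = -np.inf
            i = int(np.argmax(delta))
            cur += delta[i]
            s_work[i] = -s_work[i]
            yw += 2.0 * s_work[i] * Bg[:, i]
            moved[i] = True
            order[step] = i
            running[step] = cur
        best = int(np.argmax(running))
        if running[best] > q0 + _TOL:
            s[order[: best + 1]] *= -1
        else:
            return s


def _bisect(Bg: np.ndarray, refine: bool) -> Tuple[np.ndarray, float]:
    """Leading-eigenvector bisection; returns (sign vector, s^T B s)."""
    n = Bg.shape[0]
    eigval, eigvec = linalg.eigh(Bg, subset_by_index=[n - 1, n - 1])
    v = eigvec[:, 0]
    s = np.where(v >= 0.0, 1.0, -1.0)  # zero entries join group +
    if refine:
        s = _kl_refine(Bg, s)
    return s, float(s @ Bg @ s)


def newman_spectral(net, refine: bool = True, weighted: bool = False) -> Partition:
    """Extract communities by recursive spectral bisection.

    Connected components are handled independently (each starts as its
    own group).  Deterministic: nodes are processed in sorted order and
    the sign ambiguity of each eigenvector is resolved by placing the
    lexicographically smallest node of the group in the + side.
    """
    g = _as_graph(net, weighted=weighted)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight" if weighted else None)
    k = A.sum(axis=1)
    m2 = k.sum()
    if m2 == 0:
        labels = {n: i for i, n in enumerate(nodes)}
        return Partition(labels=labels, Q=0.0, method_meta={"refine": refine})

    final_groups: List[np.ndarray] = []
    idx = {n: i for i, n in enumerate(nodes)}
    stack: List[np.ndarray] = [
        np.array(sorted(idx[n] for n in comp))
        for comp in nx.connected_components(g)
    ]
    stack.sort(key=lambda arr: arr[0])

    while stack:
        grp = stack.pop()
        if len(grp) == 1:
            final_groups.append(grp)
            continue
        Bg = A[np.ix_(grp, grp)] - np.outer(k[grp], k[grp]) / m2
        Bg -= np.diag(Bg.sum(axis=1))
        s, quad = _bisect(Bg, refine)
        if s[0] < 0:  # grp is sorted: entry 0 is the smallest node
            s = -s
        d_q = quad / (2.0 * m2)
        plus = grp[s > 0]
        minus = grp[s < 0]
        if d_q > _TOL and len(plus) and len(minus):
            stack.append(plus)
            stack.append(minus)
        else:
            final_groups.append(grp)

    final_groups.sort(key=lambda arr: arr[0])
    labels = {}
    for c, grp in enumerate(final_groups):
        for i in grp:
            labels[nodes[i]] = c
    q = modularity(g, labels, weighted=weighted)
    return Partition(labels=labels, Q=q, method_meta={"refine": refine, "weighted": weighted})


def modularity(net, labels, weighted: bool = False) -> float:
    """Q = sum_c (e_cc - a_c^2) on the (by default binarized) graph."""
    g = _as_graph(net, weighted=weighted)
    if isinstance(labels, Partition):
        labels = labels.labels
    missing = set(g.nodes) - set(labels)
    if missing:
        raise ValueError(f"unlabelled nodes: {sorted(missing)[:5]}")
    m2 = 0.0
    within = {}
    deg = {}
    for a, b, data in g.edges(data=True):
        w = data.get("weight", 1.0) if weighted else 1.0
        m2 += 2 * w
        deg[labels[a]] = deg.get(labels[a], 0.0) + w
        deg[labels[b]] = deg.get(labels[b], 0.0) + w
        if labels[a] == labels[b]:
            within[labels[a]] = within.get(labels[a], 0.0) + w
    if m2 == 0:
        return 0.0
    q = 0.0
    for c in set(labels.values()):
        e_cc = 2 * within.get(c, 0.0) / m2
        a_c = deg.get(c, 0.0) / m2
        q += e_cc - a_c**2
    return float(q)


def hubs(net, percentile: float = 80.0) -> Set[str]:
    """Nodes with degree strictly above the given degree percentile.

    With the default 80th percentile this selects (at most) the top 20%
    most connected nodes; in a regular graph no node exceeds the
    threshold and the set is empty.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie strictly between 0 and 100")
    g = _as_graph(net)
    degs = dict(g.degree())
    if not degs:
        return set()
    thr = float(np.percentile(np.array(list(degs.values()), dtype=float), percentile))
    return {n for n, d in degs.items() if d > thr}
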