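"""Ontology handling: OBO parsing, term levels, granularity weights.

An ontology here is a rooted DAG of terms connected by ``is_a`` links.
The *level* of a term is the length of the shortest path from the root
(the root's children are level 1).  For a fixed annotation set, ``n_j``
counts the strict descendants of term *j* that carry at least one
annotation, and the granularity weight ``g_j`` is a decreasing (scheme
"inverse", the default) or increasing (scheme "linear") function of
``n_j``.  These weights later populate the weighted biadjacency matrix.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set

import networkx as nx
import obonet

__all__ = [
    "OntologyTerm",
    "OntologyDAG",
    "OntologyError",
    "parse_obo",
    "granularity_weight",
    "level_usage_histogram",
    "GRANULARITY_SCHEMES",
]


class OntologyError(ValueError):
    """Structural or lookup error in an ontology DAG."""


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    parents: frozenset = frozenset()
    obsolete: bool = False


GRANULARITY_SCHEMES = ("inverse", "linear")


def granularity_weight(n_j: int, scheme: str = "inverse") -> float:
    """Weight of a term with ``n_j`` annotated descendants.

    "inverse" (default) down-weights broad terms: g = 1/(1+n);
    "linear" up-weights them: g = 1+n.
    """
    if n_j < 0:
        raise OntologyError(f"n_j must be non-negative, got {n_j}")
    if scheme == "inverse":
        return 1.0 / (1.0 + n_j)
    if scheme == "linear":
        return 1.0 + float(n_j)
    raise OntologyError(f"unknown granularity scheme {scheme!r}")


@dataclass
class OntologyDAG:
    """Rooted DAG of ontology terms with levels and granularity weights.

    Only ``is_a`` relationships define edges.  Obsolete terms are dropped
    at parse time.  ``level`` maps each term to its shortest-path distance
    from the root (root itself is level 0).
    """

    terms: Dict[str, OntologyTerm]
    root: str
    level: Dict[str, int] = field(default_factory=dict)
    n_annotated_below: Dict[str, int] = field(default_factory=dict)
    granularity: Dict[str, float] = field(default_factory=dict)
    granularity_scheme: Optional[str] = None
    _children: Dict[str, Set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._children = {t: set() for t in self.terms}
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise OntologyError(
                        f"term {t.term_id} references unknown parent {p}"
                    )
                self._children[p].add(t.term_id)
        if not self.level:
            self.compute_levels()

    # -- construction -------------------------------------------------

    @classmethod
    def from_terms(cls, terms: Iterable[OntologyTerm]) -> "OntologyDAG":
        tmap = {t.term_id: t for t in terms if not t.obsolete}
        roots = sorted(t for t, term in tmap.items() if not term.parents)
        if len(roots) != 1:
            raise OntologyError(
                f"expected a single root term, found {len(roots)}: {roots[:5]}"
            )
        return cls(terms=tmap, root=roots[0])

    def compute_levels(self) -> "OntologyDAG":
        """BFS levels from the root; raises on cycles or unreachable terms."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                g.add_edge(p, t.term_id)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OntologyError(f"ontology contains a cycle: {cyc}")
        level = {self.root: 0}
        q = deque([self.root])
        while q:
            u = q.popleft()
            for c in self._children[u]:
                if c not in level:
                    level[c] = level[u] + 1
                    q.append(c)
        missing = set(self.terms) - set(level)
        if missing:
            raise OntologyError(
                f"{len(missing)} terms unreachable from root {self.root}: "
                f"{sorted(missing)[:5]}"
            )
        self.level = level
        return self

    # -- traversal ----------------------------------------------------

    def children(self, term_id: str) -> Set[str]:
        self._check(term_id)
        return set(self._children[term_id])

    def parents(self, term_id: str) -> Set[str]:
        self._check(term_id)
        return set(self.terms[term_id].parents)

    def descendants(self, term_id: str) -> Set[str]:
        """Strict descendants of a term via any parent path."""
        self._check(term_id)
        seen: Set[str] = set()
        q = deque([term_id])
        while q:
            u = q.popleft()
            for c in self._children[u]:
                if c not in seen:
                    seen.add(c)
                    q.append(c)
        return seen

    def ancestors(self, term_id: str) -> Set[str]:
        self._check(term_id)
        seen: Set[str] = set()
        q = deque([term_id])
        while q:
            u = q.popleft()
            for p in self.terms[u].parents:
                if p not in seen:
                    seen.add(p)
                    q.append(p)
        return seen

    def ancestors_at_level(self, term_id: str, L: int) -> Set[str]:
        """Ancestors-or-self of ``term_id`` lying exactly at level ``L``.

        Multi-parent terms can have several level-L ancestors, each of
        which receives an annotation contribution.  Terms above level L
        yield the empty set.
        """
        if L < 1:
            raise OntologyError(f"level must be >= 1, got {L}")
        self._check(term_id)
        if self.level[term_id] < L:
            return set()
        if self.level[term_id] == L:
            # self counts as its own descendant-or-self
            return {term_id}
        return {a for a in self.ancestors(term_id) if self.level[a] == L}

    def terms_at_level(self, L: int) -> Set[str]:
        return {t for t, lv in self.level.items() if lv == L}

    @property
    def depth(self) -> int:
        return max(self.level.values())

    # -- annotation-dependent quantities -------------------------------

    def annotated_descendants(self, annotations, term_id: str) -> Set[str]:
        """Strict descendants of ``term_id`` carrying >=1 annotation."""
        annotated = annotations.terms if hasattr(annotations, "terms") else set(annotations)
        return self.descendants(term_id) & annotated

    def compute_granularity(self, annotations, scheme: str = "inverse") -> "OntologyDAG":
        """Compute n_j and g_j for every term against a fixed annotation set.

        n_j is accumulated bottom-up so the computation is linear in the
        number of edges rather than quadratic in terms.
        """
        annotated = annotations.terms if hasattr(annotations, "terms") else set(annotations)
        annotated = annotated & set(self.terms)
        # bottom-up union of annotated descendant sets; DAGs can share
        # descendants between parents so sets (not counts) are propagated
        order = sorted(self.terms, key=lambda t: -self.level[t])
        below: Dict[str, Set[str]] = {}
        for t in order:
            acc: Set[str] = set()
            for c in self._children[t]:
                acc |= below[c]
                if c in annotated:
                    acc.add(c)
            below[t] = acc
        self.n_annotated_below = {t: len(below[t]) for t in self.terms}
        self.granularity = {
            t: granularity_weight(n, scheme) for t, n in self.n_annotated_below.items()
        }
        self.granularity_scheme = scheme
        return self

    def weight_table(self):
        """Level/weight table as a pandas DataFrame (term_id, level, n, g)."""
        import pandas as pd

        rows = [
            (t, self.level[t], self.n_annotated_below.get(t), self.granularity.get(t))
            for t in sorted(self.terms)
        ]
        return pd.DataFrame(
            rows, columns=["term_id", "level", "n_annotated_below", "granularity"]
        )

    def name_to_id(self) -> Dict[str, str]:
        return {term.name: tid for tid, term in self.terms.items()}

    def _check(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term {term_id!r}")


def parse_obo(path_or_handle) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into an :class:`OntologyDAG`.

    Only ``[Term]`` stanzas and ``is_a`` links are used; obsolete terms
    are excluded.  Levels are computed immediately (single root required).
    """
    try:
        graph = obonet.read_obo(path_or_handle, ignore_obsolete=True)
    except (ValueError, KeyError) as exc:  # pragma: no cover - message passthrough
        raise OntologyError(f"failed to parse OBO file {path_or_handle!r}: {exc}") from exc
    terms = []
    for tid, data in graph.nodes(data=True):
        parents = frozenset(data.get("is_a", []))
        terms.append(OntologyTerm(term_id=tid, name=data.get("name", tid), parents=parents))
    if not terms:
        raise OntologyError(f"no [Term] stanzas found in {path_or_handle!r}")
    return OntologyDAG.from_terms(terms)


def parse_obo_str(text: str) -> OntologyDAG:
    """Parse OBO content from a string (convenience for generated data)."""
    return parse_obo(io.StringIO(text))


def level_usage_histogram(annotations, dag: OntologyDAG) -> Dict[int, int]:
    """Counts of raw annotation records per term level.

    The sum over levels equals the number of annotation records whose
    term is present in the DAG.
    """
    hist: Dict[int, int] = {}
    for rec in annotations.records:
        lv = dag.level.get(rec.term_id)
        if lv is None:
            continue
        hist[lv] = hist.get(lv, 0) + 1
    return dict(sorted(hist.items()))
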