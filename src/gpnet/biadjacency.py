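"""Weighted gene x phenotype biadjacency matrix at a chosen ontology level.

For analysis level L, each annotated term t of gene i contributes its
granularity weight g_t to every level-L column j that is an
ancestor-or-self of t (multi-parent terms therefore contribute to several
columns).  B_ij is the sum of those contributions.

Besides the dense matrix, the builder retains the per-cell contribution
detail (which annotated terms, with which weights, stand behind each
B_ij); the association module consumes that detail to form the per-column
weight vectors compared by the Wilcoxon test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .ontology import OntologyDAG, OntologyError

__all__ = ["WeightedBiadjacency", "build_biadjacency"]


@dataclass
class WeightedBiadjacency:
    """Dense non-negative matrix with labelled rows and columns.

    ``axis_kind`` records whether rows are genes and columns terms
    ("gene" orientation) or the transpose.  ``cells`` maps
    (row_id, col_id) -> {term: weight} contribution detail and is carried
    through :meth:`transpose` unchanged apart from key order.
    """

    row_ids: List[str]
    col_ids: List[str]
    values: np.ndarray
    level: int
    axis_kind: str = "gene"  # rows are genes ("gene") or terms ("phenotype")
    cells: Optional[Dict[Tuple[str, str], Dict[str, float]]] = field(
        default=None, repr=False
    )

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match row/col labels")
        if (self.values < 0).any():
            raise ValueError("biadjacency entries must be non-negative")
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}
        self._col_index = {c: i for i, c in enumerate(self.col_ids)}

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self._row_index[row_id]]

    def transpose(self) -> "WeightedBiadjacency":
        """Swap rows and columns; contribution detail follows."""
        cells = None
        if self.cells is not None:
            cells = {(c, r): d for (r, c), d in self.cells.items()}
        return WeightedBiadjacency(
            row_ids=list(self.col_ids),
            col_ids=list(self.row_ids),
            values=self.values.T.copy(),
            level=self.level,
            axis_kind="phenotype" if self.axis_kind == "gene" else "gene",
            cells=cells,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    def write_mtx(self, path) -> None:
        from scipy import io as sio
        from scipy import sparse

        sio.mmwrite(str(path), sparse.csr_matrix(self.values))

    @classmethod
    def read_tsv(cls, path, level: int = 0, axis_kind: str = "gene"):
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            row_ids=[str(i) for i in df.index],
            col_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            level=level,
            axis_kind=axis_kind,
        )


def build_biadjacency(
    annotations,
    dag: OntologyDAG,
    L: int,
    granularity_scheme: str = "inverse",
    include_level_self: bool = True,
    drop_empty_columns: bool = True,
) -> WeightedBiadjacency:
    """Build the weighted biadjacency matrix B at level ``L``.

    Granularity weights are (re)computed against ``annotations`` with the
    requested scheme.  A term exactly at level L counts as its own
    descendant-or-self unless ``include_level_self`` is False (in which
    case only strictly deeper annotations contribute).  All-zero columns
    are dropped by default; row and column order is lexicographic.
    """
    if L < 1:
        raise OntologyError(f"level must be >= 1, got {L}")
    if L > dag.depth:
        raise OntologyError(f"level {L} exceeds ontology depth {dag.depth}")
    if not len(annotations):
        raise ValueError("empty annotation set")
    if dag.granularity_scheme != granularity_scheme or not dag.granularity:
        dag.compute_granularity(annotations, scheme=granularity_scheme)

    # ancestor columns are shared across genes annotated to the same term
    anc_cache: Dict[str, frozenset] = {}

    def columns_for(term: str) -> frozenset:
        hit = anc_cache.get(term)
        if hit is None:
            cols = dag.ancestors_at_level(term, L)
            if not include_level_self:
                cols.discard(term)
            hit = frozenset(cols)
            anc_cache[term] = hit
        return hit

    cells: Dict[Tuple[str, str], Dict[str, float]] = {}
    for rec in annotations.records:
        if rec.term_id not in dag.terms:
            continue
        g = dag.granularity[rec.term_id]
        for col in columns_for(rec.term_id):
            cells.setdefault((rec.gene_id, col), {})[rec.term_id] = g

    if not cells:
        raise ValueError(f"no annotations map to any level-{L} column")

    genes = sorted({r for r, _ in cells})
    cols = sorted({c for _, c in cells}) if drop_empty_columns else sorted(
        dag.terms_at_level(L)
    )
    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: i for i, c in enumerate(cols)}
    values = np.zeros((len(genes), len(cols)))
    for (gene, col), contrib in cells.items():
        if col in ci:
            values[gi[gene], ci[col]] = sum(contrib.values())
    return WeightedBiadjacency(
        row_ids=genes, col_ids=cols, values=values, level=L, cells=cells
    )
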