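"""Gene-phenotype annotation ingest: parsing, merging, filtering, ID mapping.

Association reports reduce to (gene, term) pairs.  Zygosity / genotype
detail is deliberately collapsed: if any genotype of a gene shows a
phenotype the gene is associated with the term, so deduplication on the
(gene, term) pair is the collapse.  Absence of a record means "no data",
not "phenotype absent".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import pandas as pd

__all__ = [
    "AnnotationRecord",
    "AnnotationSet",
    "AnnotationError",
    "parse_report",
    "parse_mapping_table",
    "DEFAULT_EXCLUDED_TERM_NAMES",
]

#: Uninformative phenotype terms removed by default (matched by term *name*
#: via an ontology, or used directly as IDs if they appear as such).
DEFAULT_EXCLUDED_TERM_NAMES = (
    "no phenotypic analysis",
    "normal phenotype",
    "no abnormal phenotype detected",
    "phenotypic reversion",
    "reversion by mitotic recombination",
    "reversion by viral sequence excision",
)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    term_id: str
    source: str = "curated"  # curated | highthroughput | synthetic

    def __post_init__(self):
        if not self.gene_id or not self.term_id:
            raise AnnotationError("gene_id and term_id must be non-empty")


@dataclass
class AnnotationSet:
    """Non-redundant bipartite edge list of gene-term associations.

    Records are deduplicated on (gene_id, term_id); the first-seen source
    wins for a duplicated pair.
    """

    records: FrozenSet[AnnotationRecord] = frozenset()
    n_skipped: int = 0
    n_unmapped: int = 0

    def __post_init__(self):
        dedup: Dict[Tuple[str, str], AnnotationRecord] = {}
        for rec in sorted(
            self.records, key=lambda r: (r.gene_id, r.term_id, r.source)
        ):
            dedup.setdefault((rec.gene_id, rec.term_id), rec)
        self.records = frozenset(dedup.values())

    @property
    def genes(self) -> Set[str]:
        return {r.gene_id for r in self.records}

    @property
    def terms(self) -> Set[str]:
        return {r.term_id for r in self.records}

    @property
    def pairs(self) -> Set[Tuple[str, str]]:
        return {(r.gene_id, r.term_id) for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def merge(self, other: "AnnotationSet") -> "AnnotationSet":
        """Union of two sets; commutative and idempotent on pairs."""
        return AnnotationSet(
            records=self.records | other.records,
            n_skipped=self.n_skipped + other.n_skipped,
            n_unmapped=self.n_unmapped + other.n_unmapped,
        )

    def filter_excluded(self, excluded: Iterable[str]) -> "AnnotationSet":
        """Drop records annotated to any term id in ``excluded``.

        Genes whose every annotation is excluded disappear from the gene
        universe (a warning reports how many).
        """
        excluded = set(excluded)
        kept = frozenset(r for r in self.records if r.term_id not in excluded)
        lost_genes = {r.gene_id for r in self.records} - {r.gene_id for r in kept}
        if not kept and self.records:
            warnings.warn("all annotation records were excluded")
        elif lost_genes:
            warnings.warn(
                f"{len(lost_genes)} genes lost all annotations during exclusion"
            )
        return AnnotationSet(records=kept, n_skipped=self.n_skipped,
                             n_unmapped=self.n_unmapped)

    def map_ids(self, table: Dict[str, str]) -> "AnnotationSet":
        """Translate gene IDs through a source->target table.

        Unmapped genes are dropped and counted in ``n_unmapped``.
        Many-to-one mappings are safe: records deduplicate after mapping.
        """
        mapped = []
        unmapped_genes = set()
        for r in self.records:
            tgt = table.get(r.gene_id)
            if tgt is None:
                unmapped_genes.add(r.gene_id)
                continue
            mapped.append(AnnotationRecord(tgt, r.term_id, r.source))
        return AnnotationSet(
            records=frozenset(mapped),
            n_skipped=self.n_skipped,
            n_unmapped=self.n_unmapped + len(unmapped_genes),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = sorted((r.gene_id, r.term_id, r.source) for r in self.records)
        return pd.DataFrame(rows, columns=["gene_id", "term_id", "source"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def parse_report(
    path,
    gene_col: int = 0,
    term_col: int = 1,
    sep: str = "\t",
    comment: str = "#",
    source: str = "curated",
    header: bool = False,
) -> AnnotationSet:
    """Parse a TSV association report into an :class:`AnnotationSet`.

    ``gene_col``/``term_col`` select columns so that both MGI-like and
    high-throughput-export-like dialects reduce to (gene, term) pairs.
    Rows lacking either column are skipped and counted.
    """
    records: List[AnnotationRecord] = []
    n_skipped = 0
    need = max(gene_col, term_col) + 1
    with open(path, "rt", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if header and i == 0:
                continue
            line = line.rstrip("\n")
            if not line or (comment and line.startswith(comment)):
                continue
            parts = line.split(sep)
            if len(parts) < need or not parts[gene_col].strip() or not parts[term_col].strip():
                n_skipped += 1
                continue
            records.append(
                AnnotationRecord(parts[gene_col].strip(), parts[term_col].strip(), source)
            )
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} malformed rows in {path}")
    return AnnotationSet(records=frozenset(records), n_skipped=n_skipped)


def parse_mapping_table(path, sep: str = "\t", comment: str = "#") -> Dict[str, str]:
    """Read a two-column source->target gene ID table.

    Conflicting duplicate mappings raise an error listing the offenders.
    """
    table: Dict[str, str] = {}
    conflicts = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or (comment and line.startswith(comment)):
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                continue
            src, tgt = parts[0].strip(), parts[1].strip()
            if src in table and table[src] != tgt:
                conflicts.append(src)
            table[src] = tgt
    if conflicts:
        raise AnnotationError(
            f"conflicting duplicate mappings for: {sorted(set(conflicts))}"
        )
    return table


def excluded_term_ids(dag, names: Iterable[str] = DEFAULT_EXCLUDED_TERM_NAMES) -> Set[str]:
    """Resolve exclusion-list term *names* to IDs present in a DAG."""
    by_name = dag.name_to_id()
    return {by_name[n] for n in names if n in by_name}
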