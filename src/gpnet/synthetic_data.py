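"""Self-contained synthetic inputs with planted modular structure.

The generator emulates the statistical structure the downstream analysis
assumes: a rooted ontology DAG with several levels and occasional
multi-parent terms; gene modules annotated preferentially under distinct
level-1 subtrees (with an infidelity rate and a pleiotropy noise rate);
within-module correlated expression; module-biased tissue expression;
within-module-enriched protein interactions; within-module-correlated
phylogenetic profiles; and per-branch GO annotations with the same
modular bias.  Planted module labels are emitted for recovery scoring.

``null_bundle`` produces data with matching marginals but no planted
structure, for type-I-error / calibration checks.

All randomness flows from a single mandatory seed; generation is
deterministic (byte-identical files for identical seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotations import AnnotationRecord, AnnotationSet
from .ontology import OntologyDAG, parse_obo_str

__all__ = [
    "SyntheticConfig",
    "OntologyParams",
    "AnnotationParams",
    "ExpressionParams",
    "TissueParams",
    "PPIParams",
    "PhyloParams",
    "GOParams",
    "Bundle",
    "GOBranch",
    "generate",
    "null_bundle",
    "resample_auxiliary",
    "load_bundle",
]

# A couple of genetic (non-physical) evidence labels used for decoy PPI rows.
_GENETIC_SYSTEMS = ("Dosage Rescue", "Synthetic Lethality")
_PHYSICAL_SYSTEMS = ("Two-Hybrid", "Affinity Capture-MS", "Reconstituted Complex")


@dataclass(frozen=True)
class OntologyParams:
    depth: int = 8
    branching: float = 1.9
    n_level1: int = 8
    multi_parent_rate: float = 0.05


@dataclass(frozen=True)
class AnnotationParams:
    per_gene_mean: float = 8.0
    module_fidelity: float = 0.9
    level_peak: int = 5
    min_level: int = 2


@dataclass(frozen=True)
class ExpressionParams:
    n_samples: int = 200
    within_module_corr: float = 0.6


@dataclass(frozen=True)
class TissueParams:
    n_tissues: int = 30
    tissues_per_module: int = 5
    module_tissue_bias: float = 0.8
    base_rate: float = 0.15


@dataclass(frozen=True)
class PPIParams:
    within_density: float = 0.10
    between_density: float = 0.01


@dataclass(frozen=True)
class PhyloParams:
    n_species: int = 40
    within_module_corr: float = 0.6


@dataclass(frozen=True)
class GOParams:
    module_fidelity: float = 0.9
    per_gene_mean: float = 5.0
    # (depth, branching, level_peak, analysis_level) per branch
    bp: Tuple[int, float, int, int] = (6, 2.0, 5, 5)
    cc: Tuple[int, float, int, int] = (6, 2.0, 5, 5)
    mf: Tuple[int, float, int, int] = (3, 3.0, 2, 2)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterisation of a synthetic study.

    ``seed`` is mandatory; every rate / probability lies in [0, 1].
    Defaults are sized for desk-scale analysis: 300 genes in 5 modules
    under a depth-8 ontology of roughly 1500 terms.
    """

    seed: int
    n_genes: int = 300
    n_modules: int = 5
    pleiotropy_noise_rate: float = 0.05
    ontology: OntologyParams = OntologyParams()
    annotation: AnnotationParams = AnnotationParams()
    expression: ExpressionParams = ExpressionParams()
    tissue: TissueParams = TissueParams()
    ppi: PPIParams = PPIParams()
    phylo: PhyloParams = PhyloParams()
    go: GOParams = GOParams()

    def __post_init__(self):
        for name, val in [
            ("pleiotropy_noise_rate", self.pleiotropy_noise_rate),
            ("annotation.module_fidelity", self.annotation.module_fidelity),
            ("ontology.multi_parent_rate", self.ontology.multi_parent_rate),
            ("expression.within_module_corr", self.expression.within_module_corr),
            ("go.module_fidelity", self.go.module_fidelity),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.n_modules > self.ontology.n_level1:
            raise ValueError(
                f"{self.n_modules} modules need at least as many level-1 "
                f"subtrees (got {self.ontology.n_level1})"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        """Build a config from a plain (e.g. YAML-loaded) mapping."""
        nested = {
            "ontology": OntologyParams, "annotation": AnnotationParams,
            "expression": ExpressionParams, "tissue": TissueParams,
            "ppi": PPIParams, "phylo": PhyloParams,
        }
        kwargs = {}
        for k, v in d.items():
            if k in nested and isinstance(v, dict):
                kwargs[k] = nested[k](**v)
            elif k == "go" and isinstance(v, dict):
                v = dict(v)
                for b in ("bp", "cc", "mf"):
                    if b in v:
                        v[b] = tuple(v[b])
                kwargs[k] = GOParams(**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


@dataclass
class GOBranch:
    name: str
    obo_text: str
    dag: OntologyDAG
    annotations: AnnotationSet
    level: int


@dataclass
class Bundle:
    """In-memory synthetic study: inputs plus planted truth."""

    config: SyntheticConfig
    obo_text: str
    dag: OntologyDAG
    annotations: AnnotationSet
    labels: Dict[str, int]
    expression: pd.DataFrame
    tissue: pd.DataFrame
    ppi: List[Tuple[str, str, str]]
    phylo: pd.DataFrame
    go: Dict[str, GOBranch]
    kind: str = "planted"  # planted | null

    @property
    def genes(self) -> List[str]:
        return sorted(self.labels)

    def write(self, outdir) -> Dict[str, str]:
        """Write the bundle as plain-text files plus a manifest JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        files: Dict[str, Path] = {}

        def _txt(name: str, text: str) -> None:
            p = out / name
            p.write_text(text, encoding="utf-8")
            files[name] = p

        _txt("ontology.obo", self.obo_text)
        self.annotations.write_tsv(out / "annotations.tsv")
        files["annotations.tsv"] = out / "annotations.tsv"
        labels_df = pd.DataFrame(sorted(self.labels.items()), columns=["gene", "module"])
        labels_df.to_csv(out / "labels.tsv", sep="\t", index=False)
        files["labels.tsv"] = out / "labels.tsv"
        for name, df in [
            ("expression.tsv", self.expression),
            ("tissue.tsv", self.tissue),
            ("phylo.tsv", self.phylo),
        ]:
            df.to_csv(out / name, sep="\t", index_label="gene", float_format="%.6g")
            files[name] = out / name
        ppi_df = pd.DataFrame(self.ppi, columns=["gene_a", "gene_b", "evidence"])
        ppi_df.to_csv(out / "ppi.tsv", sep="\t", index=False)
        files["ppi.tsv"] = out / "ppi.tsv"
        for branch in sorted(self.go):
            gb = self.go[branch]
            _txt(f"go_{branch}.obo", gb.obo_text)
            gb.annotations.write_tsv(out / f"go_{branch}_annotations.tsv")
            files[f"go_{branch}_annotations.tsv"] = out / f"go_{branch}_annotations.tsv"
        manifest = {
            "kind": self.kind,
            "config": dataclasses.asdict(self.config),
            "go_levels": {b: self.go[b].level for b in sorted(self.go)},
            "files": {
                name: hashlib.sha256(p.read_bytes()).hexdigest()
                for name, p in sorted(files.items())
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest["files"]


# ---------------------------------------------------------------------------
# ontology generation


def _random_dag(
    rng: np.random.Generator,
    depth: int,
    branching: float,
    n_level1: int,
    multi_parent_rate: float,
    prefix: str,
) -> Tuple[str, Dict[str, int], Dict[str, int]]:
    """Random rooted DAG as OBO text.

    Returns (obo_text, subtree map term->level-1 index, level map).  Each
    level-1 subtree keeps a guaranteed spine down to ``depth`` so every
    subtree offers terms at every level; extra (multi-)parents are drawn
    within the same subtree one level up, preserving both subtree
    disjointness and shortest-path levels.
    """
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{prefix}:{counter[0]:07d}"

    root = new_id()
    parents: Dict[str, List[str]] = {root: []}
    level: Dict[str, int] = {root: 0}
    subtree: Dict[str, int] = {}
    by_level_subtree: Dict[Tuple[int, int], List[str]] = {}

    for s in range(n_level1):
        t = new_id()
        parents[t] = [root]
        level[t] = 1
        subtree[t] = s
        by_level_subtree[(1, s)] = [t]

    for lv in range(2, depth + 1):
        for s in range(n_level1):
            prev = by_level_subtree.get((lv - 1, s), [])
            cur: List[str] = []
            for i, parent in enumerate(prev):
                n_children = int(rng.poisson(branching))
                if i == 0 and n_children == 0:
                    n_children = 1  # spine: keep every subtree at full depth
                for _ in range(n_children):
                    t = new_id()
                    parents[t] = [parent]
                    level[t] = lv
                    subtree[t] = s
                    cur.append(t)
                    if len(prev) > 1 and rng.random() < multi_parent_rate:
                        extra = prev[int(rng.integers(0, len(prev)))]
                        if extra != parent:
                            parents[t].append(extra)
            by_level_subtree[(lv, s)] = cur

    lines = ["format-version: 1.2", f"ontology: {prefix.lower()}", ""]
    for t in sorted(parents):
        lines.append("[Term]")
        lines.append(f"id: {t}")
        lines.append(f"name: term {t}")
        for p in sorted(parents[t]):
            lines.append(f"is_a: {p} ! term {p}")
        lines.append("")
    return "\n".join(lines) + "\n", subtree, level


def _level_weights(levels: Sequence[int], peak: int, sd: float = 1.2) -> np.ndarray:
    lv = np.asarray(levels, dtype=float)
    w = np.exp(-0.5 * ((lv - peak) / sd) ** 2)
    return w / w.sum()


def _draw_annotations(
    rng: np.random.Generator,
    genes: Sequence[str],
    labels: Dict[str, int],
    subtree: Dict[str, int],
    level: Dict[str, int],
    n_subtrees: int,
    per_gene_mean: float,
    fidelity: float,
    noise_rate: float,
    level_peak: int,
    min_level: int,
) -> AnnotationSet:
    """Module-biased annotation draw over a generated DAG."""
    terms_by_subtree_level: Dict[Tuple[int, int], List[str]] = {}
    all_terms: List[str] = []
    for t, s in subtree.items():
        if level[t] >= min_level:
            terms_by_subtree_level.setdefault((s, level[t]), []).append(t)
            all_terms.append(t)
    for key in terms_by_subtree_level:
        terms_by_subtree_level[key].sort()
    all_terms.sort()
    levels_by_subtree: Dict[int, List[int]] = {}
    for (s, lv) in terms_by_subtree_level:
        levels_by_subtree.setdefault(s, []).append(lv)
    for s in levels_by_subtree:
        levels_by_subtree[s].sort()

    records = []
    for gene in genes:
        own = labels[gene] % n_subtrees
        k = max(1, int(rng.poisson(per_gene_mean)))
        for _ in range(k):
            if rng.random() < noise_rate:
                term = all_terms[int(rng.integers(0, len(all_terms)))]
            else:
                if rng.random() < fidelity or n_subtrees == 1:
                    s = own
                else:
                    others = [i for i in range(n_subtrees) if i != own]
                    s = others[int(rng.integers(0, len(others)))]
                lvs = levels_by_subtree[s]
                w = _level_weights(lvs, level_peak)
                lv = lvs[int(rng.choice(len(lvs), p=w))]
                pool = terms_by_subtree_level[(s, lv)]
                term = pool[int(rng.integers(0, len(pool)))]
            records.append(AnnotationRecord(gene, term, "synthetic"))
    return AnnotationSet(records=frozenset(records))


# ---------------------------------------------------------------------------
# auxiliary data


def _expression(rng, genes, labels, n_samples, rho) -> pd.DataFrame:
    modules = sorted(set(labels.values()))
    factors = {m: rng.standard_normal(n_samples) for m in modules}
    rows = []
    for g in genes:
        eps = rng.standard_normal(n_samples)
        x = np.sqrt(rho) * factors[labels[g]] + np.sqrt(1.0 - rho) * eps
        rows.append(x)
    cols = [f"sample{i:03d}" for i in range(n_samples)]
    return pd.DataFrame(np.array(rows), index=list(genes), columns=cols)


def _tissue(rng, genes, labels, params: TissueParams, planted: bool) -> pd.DataFrame:
    nt = params.n_tissues
    pref: Dict[int, set] = {}
    for m in sorted(set(labels.values())):
        start = (m * params.tissues_per_module) % nt
        pref[m] = {(start + i) % nt for i in range(params.tissues_per_module)}
    p_null = (
        params.tissues_per_module * params.module_tissue_bias
        + (nt - params.tissues_per_module) * params.base_rate
    ) / nt
    rows = []
    for g in genes:
        probs = np.full(nt, p_null)
        if planted:
            probs = np.array([
                params.module_tissue_bias if t in pref[labels[g]] else params.base_rate
                for t in range(nt)
            ])
        rows.append((rng.random(nt) < probs).astype(int))
    cols = [f"tissue{i:02d}" for i in range(nt)]
    return pd.DataFrame(np.array(rows), index=list(genes), columns=cols)


def _ppi(rng, genes, labels, params: PPIParams, planted: bool) -> List[Tuple[str, str, str]]:
    genes = list(genes)
    n = len(genes)
    n_within = sum(
        1 for i in range(n) for j in range(i + 1, n) if labels[genes[i]] == labels[genes[j]]
    )
    n_total = n * (n - 1) // 2
    pooled = (
        params.within_density * n_within
        + params.between_density * (n_total - n_within)
    ) / n_total
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            same = labels[genes[i]] == labels[genes[j]]
            p = (params.within_density if same else params.between_density) if planted else pooled
            if rng.random() < p:
                ev = _PHYSICAL_SYSTEMS[int(rng.integers(0, len(_PHYSICAL_SYSTEMS)))]
                edges.append((genes[i], genes[j], ev))
            elif rng.random() < params.between_density:
                # decoy genetic-evidence rows exercise the physical filter
                ev = _GENETIC_SYSTEMS[int(rng.integers(0, len(_GENETIC_SYSTEMS)))]
                edges.append((genes[i], genes[j], ev))
    return edges


def _phylo(rng, genes, labels, params: PhyloParams, planted: bool) -> pd.DataFrame:
    rho = params.within_module_corr if planted else 0.0
    modules = sorted(set(labels.values()))
    base = {m: rng.standard_normal(params.n_species) for m in modules}
    rows = []
    for g in genes:
        eps = rng.standard_normal(params.n_species)
        latent = np.sqrt(rho) * base[labels[g]] + np.sqrt(1.0 - rho) * eps
        copies = np.clip(np.round(1.0 + latent), 0, 6).astype(int)
        rows.append(copies)
    cols = [f"species{i:02d}" for i in range(params.n_species)]
    return pd.DataFrame(np.array(rows), index=list(genes), columns=cols)


# ---------------------------------------------------------------------------
# top-level generation


def _build(config: SyntheticConfig, planted: bool) -> Bundle:
    rng = np.random.default_rng(config.seed)
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    labels = {g: (i * config.n_modules) // config.n_genes for i, g in enumerate(genes)}

    op = config.ontology
    obo_text, subtree, level = _random_dag(
        rng, op.depth, op.branching, op.n_level1, op.multi_parent_rate, "PT"
    )
    dag = parse_obo_str(obo_text)

    ap = config.annotation
    fidelity = ap.module_fidelity if planted else 1.0 / op.n_level1
    annots = _draw_annotations(
        rng, genes, labels, subtree, level, op.n_level1,
        ap.per_gene_mean, fidelity, config.pleiotropy_noise_rate,
        ap.level_peak, ap.min_level,
    )

    ep = config.expression
    expr = _expression(rng, genes, labels, ep.n_samples,
                       ep.within_module_corr if planted else 0.0)
    tissue = _tissue(rng, genes, labels, config.tissue, planted)
    ppi = _ppi(rng, genes, labels, config.ppi, planted)
    phylo = _phylo(rng, genes, labels, config.phylo, planted)

    gp = config.go
    go: Dict[str, GOBranch] = {}
    prefixes = {"bp": "GB", "cc": "GC", "mf": "GM"}
    go_fid = gp.module_fidelity if planted else None
    for branch in ("bp", "cc", "mf"):
        depth, branching, peak, ana_level = getattr(gp, branch)
        n_sub = max(config.n_modules, 5)
        g_obo, g_sub, g_lv = _random_dag(
            rng, depth, branching, n_sub, op.multi_parent_rate, prefixes[branch]
        )
        fid = go_fid if go_fid is not None else 1.0 / n_sub
        g_ann = _draw_annotations(
            rng, genes, labels, g_sub, g_lv, n_sub,
            gp.per_gene_mean, fid, config.pleiotropy_noise_rate,
            peak, min(2, depth),
        )
        go[branch] = GOBranch(
            name=branch, obo_text=g_obo, dag=parse_obo_str(g_obo),
            annotations=g_ann, level=ana_level,
        )

    return Bundle(
        config=config, obo_text=obo_text, dag=dag, annotations=annots,
        labels=labels, expression=expr, tissue=tissue, ppi=ppi,
        phylo=phylo, go=go, kind="planted" if planted else "null",
    )


def generate(config: SyntheticConfig) -> Bundle:
    """Generate a bundle with planted modular structure."""
    return _build(config, planted=True)


def null_bundle(config: SyntheticConfig) -> Bundle:
    """Same marginals, no planted structure (annotation fidelity at
    chance, uncorrelated expression/phylo, uniform PPI density, unbiased
    tissue profile)."""
    return _build(config, planted=False)


def _subtree_map(dag: OntologyDAG) -> Tuple[Dict[str, int], int]:
    """Map every term to the index of its level-1 subtree.

    Multi-parent links stay within one subtree by construction, so the
    level-1 ancestor set of any term resolves to a single subtree.
    """
    level1 = sorted(dag.terms_at_level(1))
    index = {t: i for i, t in enumerate(level1)}
    out: Dict[str, int] = {}
    for t, lv in dag.level.items():
        if lv == 1:
            out[t] = index[t]
        elif lv > 1:
            anc = dag.ancestors_at_level(t, 1)
            out[t] = index[sorted(anc)[0]]
    return out, len(level1)


def resample_auxiliary(bundle: Bundle, seed: int) -> Bundle:
    """Fresh auxiliary data (expression, tissue, PPI, phylo, GO
    annotations) under the bundle's own regime, keeping the ontology,
    the phenotype annotations and the planted labels fixed.

    Supports calibration studies: under the null regime every resample
    is an independent draw of the data the enrichment battery consumes.
    """
    rng = np.random.default_rng(seed)
    planted = bundle.kind == "planted"
    cfg = bundle.config
    genes = bundle.genes
    labels = bundle.labels
    expr = _expression(rng, genes, labels, cfg.expression.n_samples,
                       cfg.expression.within_module_corr if planted else 0.0)
    tissue = _tissue(rng, genes, labels, cfg.tissue, planted)
    ppi = _ppi(rng, genes, labels, cfg.ppi, planted)
    phylo = _phylo(rng, genes, labels, cfg.phylo, planted)
    go: Dict[str, GOBranch] = {}
    for branch in sorted(bundle.go):
        gb = bundle.go[branch]
        _, _, peak, _ = getattr(cfg.go, branch)
        sub, n_sub = _subtree_map(gb.dag)
        fid = cfg.go.module_fidelity if planted else 1.0 / n_sub
        ann = _draw_annotations(
            rng, genes, labels, sub, gb.dag.level, n_sub,
            cfg.go.per_gene_mean, fid, cfg.pleiotropy_noise_rate,
            peak, min(2, max(gb.dag.level.values())),
        )
        go[branch] = GOBranch(name=branch, obo_text=gb.obo_text, dag=gb.dag,
                              annotations=ann, level=gb.level)
    return Bundle(
        config=cfg, obo_text=bundle.obo_text, dag=bundle.dag,
        annotations=bundle.annotations, labels=labels,
        expression=expr, tissue=tissue, ppi=ppi, phylo=phylo,
        go=go, kind=bundle.kind,
    )


def load_bundle(indir) -> Bundle:
    """Reload a written bundle (planted labels included)."""
    from .annotations import parse_report

    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    config = SyntheticConfig.from_dict(manifest["config"])
    obo_text = (indir / "ontology.obo").read_text()
    annots = parse_report(indir / "annotations.tsv", header=True, source="synthetic")
    labels_df = pd.read_csv(indir / "labels.tsv", sep="\t")
    labels = {str(g): int(m) for g, m in labels_df.itertuples(index=False, name=None)}
    expr = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0)
    tissue = pd.read_csv(indir / "tissue.tsv", sep="\t", index_col=0)
    phylo = pd.read_csv(indir / "phylo.tsv", sep="\t", index_col=0)
    ppi_df = pd.read_csv(indir / "ppi.tsv", sep="\t")
    ppi = [tuple(r) for r in ppi_df.itertuples(index=False, name=None)]
    go = {}
    for branch, lvl in manifest["go_levels"].items():
        g_obo = (indir / f"go_{branch}.obo").read_text()
        g_ann = parse_report(
            indir / f"go_{branch}_annotations.tsv", header=True, source="synthetic"
        )
        go[branch] = GOBranch(
            name=branch, obo_text=g_obo, dag=parse_obo_str(g_obo),
            annotations=g_ann, level=int(lvl),
        )
    return Bundle(
        config=config, obo_text=obo_text, dag=parse_obo_str(obo_text),
        annotations=annots, labels=labels, expression=expr, tissue=tissue,
        ppi=ppi, phylo=phylo, go=go, kind=manifest["kind"],
    )
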