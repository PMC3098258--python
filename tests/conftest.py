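"""Shared fixtures: handcrafted ontologies and the synthetic study bundle."""

import warnings

import pytest

from gpnet.annotations import AnnotationRecord, AnnotationSet
from gpnet.ontology import parse_obo_str
from gpnet.pipeline import PipelineParams, run_all
from gpnet.synthetic_data import SyntheticConfig, generate

#: the study conditions: 300 genes, 5 modules, annotation fidelity 0.9,
#: pleiotropy noise 0.05 (generator defaults), fixed seed
STUDY_SEED = 1

# root R; level-1 A, B; under A: a1, a2 and a deeper chain a2->a3;
# d1 is a diamond child of both a1 and a2; under B: b1.
TINY_OBO = """format-version: 1.2
ontology: tiny

[Term]
id: T:R
name: root

[Term]
id: T:A
name: branch A
is_a: T:R ! root

[Term]
id: T:B
name: branch B
is_a: T:R ! root

[Term]
id: T:a1
name: a one
is_a: T:A ! branch A

[Term]
id: T:a2
name: a two
is_a: T:A ! branch A

[Term]
id: T:a3
name: a three
is_a: T:a2 ! a two

[Term]
id: T:d1
name: diamond
is_a: T:a1 ! a one
is_a: T:a2 ! a two

[Term]
id: T:b1
name: b one
is_a: T:B ! branch B
"""


@pytest.fixture()
def tiny_dag():
    return parse_obo_str(TINY_OBO)


def annset(*pairs):
    return AnnotationSet(
        records=frozenset(AnnotationRecord(g, t, "synthetic") for g, t in pairs)
    )


@pytest.fixture(scope="session")
def study_bundle():
    return generate(SyntheticConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_result(study_bundle):
    """Full pipeline on the planted study bundle (rewiring run separately)."""
    params = PipelineParams(
        n_boot=200, run_rewire=False, phen_n_boot=1000, seed=7
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(study_bundle, params)
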