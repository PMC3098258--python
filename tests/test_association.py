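"""Pairwise d scores: rank-sum engine, FDR, aggregation, thresholding."""

import itertools

import numpy as np
import pytest

from gpnet.association import (
    AssociationMatrix,
    aggregate_d,
    build_network,
    fdr_correct,
    pair_phenotype_score,
    pairwise_association,
    suggest_cutoff,
    wilcoxon_rank_sum_p,
)
from gpnet.biadjacency import build_biadjacency

from conftest import annset


def enumeration_p(u, v):
    """Exhaustive two-sided rank-sum p over all group assignments."""
    from scipy.stats import rankdata

    comb = np.concatenate([u, v])
    n1 = len(u)
    ranks = rankdata(comb)
    mu = n1 * len(v) / 2.0

    def ustat(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    obs = abs(ustat(range(n1)) - mu)
    total = hits = 0
    for idx in itertools.combinations(range(len(comb)), n1):
        total += 1
        if abs(ustat(idx) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_identical_samples_give_one(self):
        assert wilcoxon_rank_sum_p([1, 1, 2], [1, 2, 1]) == pytest.approx(1.0)
        assert wilcoxon_rank_sum_p([0.5] * 4, [0.5] * 4) == 1.0

    def test_exact_matches_enumeration_without_ties(self):
        u, v = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert wilcoxon_rank_sum_p(u, v) == pytest.approx(enumeration_p(u, v))
        u, v = [1.0, 5.0, 2.5], [4.0, 0.5, 6.0]
        assert wilcoxon_rank_sum_p(u, v) == pytest.approx(enumeration_p(u, v))

    def test_separated_weight_vectors_reject(self):
        # five annotated terms against five zeros: both the tie-corrected
        # approximation and exhaustive enumeration call this dissimilar
        u, v = np.ones(5), np.zeros(5)
        assert wilcoxon_rank_sum_p(u, v) < 0.01
        assert enumeration_p(u, v) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum_p([], [1.0])


class TestFDR:
    def test_bh_hand_example(self):
        q = fdr_correct([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_correct([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_and_dominating(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(200)
        q = fdr_correct(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([])


class TestAggregate:
    def test_single_shared_column_scale(self):
        # one corrected similarity of 0.9 among 100 columns
        assert aggregate_d([0.9], 100) == pytest.approx(0.009)

    def test_no_shared_columns(self):
        assert aggregate_d([], 5) == 0.0

    def test_identical_genes_three_of_ten(self):
        assert aggregate_d([1.0, 1.0, 1.0], 10) == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            aggregate_d([1.5], 3)


@pytest.fixture()
def three_gene_B(tiny_dag):
    # g1 and g2 identically annotated under branch A; g3 under branch B
    ann = annset(("g1", "T:a1"), ("g1", "T:a2"),
                 ("g2", "T:a1"), ("g2", "T:a2"),
                 ("g3", "T:b1"))
    return build_biadjacency(ann, tiny_dag, 1)


class TestPairScore:
    def test_identical_profiles_score_one(self, three_gene_B):
        assert pair_phenotype_score(three_gene_B, "g1", "g2", "T:A") == 1.0

    def test_unshared_column_is_no_signal(self, three_gene_B):
        assert pair_phenotype_score(three_gene_B, "g1", "g3", "T:A") is None
        assert pair_phenotype_score(three_gene_B, "g1", "g3", "T:B") is None

    def test_either_gate_scores_one_sided_pairs(self, three_gene_B):
        p = pair_phenotype_score(three_gene_B, "g1", "g3", "T:A", gate="either")
        assert p is not None and 0.0 < p <= 1.0

    def test_same_gene_rejected(self, three_gene_B):
        with pytest.raises(ValueError):
            pair_phenotype_score(three_gene_B, "g1", "g1", "T:A")


class TestPairwiseAssociation:
    def test_hand_computed_three_gene_example(self, three_gene_B):
        A = pairwise_association(three_gene_B)
        # identical genes: q=1 on their 1 shared column of 2 -> d = 0.5
        assert A.d("g1", "g2") == pytest.approx(0.5)
        # no shared level-1 phenotype -> exactly zero
        assert A.d("g1", "g3") == 0.0
        assert A.d("g2", "g3") == 0.0

    def test_phenotype_pipeline_is_transposed_gene_pipeline(self, three_gene_B):
        P = pairwise_association(three_gene_B.transpose())
        assert P.kind == "phenotype"
        assert set(P.ids) == {"T:A", "T:B"}
        assert P.values.min() >= 0 and P.values.max() <= 1
        # A and B share no gene -> zero association
        assert P.d("T:A", "T:B") == 0.0

    def test_store_per_phenotype(self, three_gene_B):
        A = pairwise_association(three_gene_B, store_per_phenotype=True)
        store = A.per_phenotype_store
        assert set(store["column"]) == {"T:A"}
        assert store["q"].between(0, 1).all()


class TestNetwork:
    def matrix(self):
        ids = ["a", "b", "c", "d"]
        vals = np.zeros((4, 4))
        pairs = {(0, 1): 0.9, (0, 2): 0.6, (1, 2): 0.7, (2, 3): 0.2}
        for (i, j), w in pairs.items():
            vals[i, j] = vals[j, i] = w
        return AssociationMatrix(ids=ids, values=vals, level=1)

    def test_zero_cutoff_keeps_all_nonzero(self):
        net = build_network(self.matrix(), 0.0)
        assert len(net.edges) == 4

    def test_cutoff_selects_exact_edges(self):
        net = build_network(self.matrix(), 0.5)
        assert [(a, b) for a, b, _ in net.edges] == [("a", "b"), ("a", "c"), ("b", "c")]
        assert "d" not in net.nodes

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="zero edges"):
            net = build_network(self.matrix(), 0.95)
        assert net.edges == []

    def test_cutoff_out_of_range(self):
        with pytest.raises(ValueError):
            build_network(self.matrix(), 1.5)

    def test_suggest_cutoff_quantile(self):
        A = self.matrix()
        got = suggest_cutoff(A, 0.5)
        assert got == pytest.approx(np.quantile([0.9, 0.6, 0.7, 0.2], 0.5))

    def test_suggest_cutoff_constant_matrix(self):
        vals = np.full((3, 3), 0.4)
        np.fill_diagonal(vals, 0)
        A = AssociationMatrix(ids=["a", "b", "c"], values=vals, level=1)
        assert suggest_cutoff(A, 0.9) == pytest.approx(0.4)

    def test_all_zero_matrix_rejected(self):
        A = AssociationMatrix(ids=["a", "b"], values=np.zeros((2, 2)), level=1)
        with pytest.raises(ValueError):
            suggest_cutoff(A, 0.9)

    def test_edge_list_roundtrip(self, tmp_path):
        net = build_network(self.matrix(), 0.5)
        p = tmp_path / "net.tsv"
        net.write_tsv(p)
        from gpnet.association import NetworkEdgeList

        back = NetworkEdgeList.read_tsv(p)
        assert back.edges == net.edges


def test_association_matrix_validates_contract():
    with pytest.raises(ValueError, match="symmetric"):
        AssociationMatrix(ids=["a", "b"], values=np.array([[0, 1], [0.5, 0]]),
                          level=1)
    with pytest.raises(ValueError, match="0, 1"):
        AssociationMatrix(ids=["a", "b"], values=np.array([[0, 2.0], [2.0, 0]]),
                          level=1)
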