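"""Within-community enrichment against resampled controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gpnet.enrichment import (
    BIOGRID_PHYSICAL_SYSTEMS,
    compare_distributions,
    correlation_matrix,
    hub_go_fisher,
    level1_sharing_chisq,
    load_ppi,
    metric_enrichment,
    ppi_count_enrichment,
    resampled_control,
    within_community_values,
)
from gpnet.biadjacency import WeightedBiadjacency


def square(ids, fill=0.0):
    vals = np.full((len(ids), len(ids)), fill, dtype=float)
    np.fill_diagonal(vals, 1.0)
    return pd.DataFrame(vals, index=ids, columns=ids)


class TestWithinValues:
    def test_three_member_community_gives_three_pairs(self):
        mat = square(list("abc"), fill=0.3)
        got = within_community_values({"a": 0, "b": 0, "c": 0}, mat)
        assert len(got) == 3
        assert np.allclose(got, 0.3)

    def test_singletons_contribute_nothing(self):
        mat = square(list("ab"))
        assert len(within_community_values({"a": 0, "b": 1}, mat)) == 0

    def test_hand_enumeration(self):
        ids = list("abcd")
        vals = np.arange(16, dtype=float).reshape(4, 4)
        vals = (vals + vals.T) / 2
        mat = pd.DataFrame(vals, index=ids, columns=ids)
        got = within_community_values({"a": 0, "b": 0, "c": 1, "d": 1}, mat)
        assert sorted(got) == sorted([mat.loc["a", "b"], mat.loc["c", "d"]])

    def test_missing_genes_warn(self):
        mat = square(list("ab"))
        with pytest.warns(UserWarning, match="missing"):
            within_community_values({"a": 0, "b": 0, "z": 0}, mat)


class TestControl:
    def test_reproducible(self):
        mat = square(list("abcdefgh"), fill=0.2)
        a = resampled_control([3, 2], list("abcdefgh"), mat, n_boot=5, seed=1)
        b = resampled_control([3, 2], list("abcdefgh"), mat, n_boot=5, seed=1)
        assert np.array_equal(a, b)

    def test_uniform_matrix_constant_mean(self):
        mat = square(list("abcdefgh"), fill=0.7)
        got = resampled_control([4], list("abcdefgh"), mat, n_boot=20, seed=0)
        assert np.allclose(got, 0.7)

    def test_planted_control_below_within(self):
        rng = np.random.default_rng(0)
        ids = [f"g{i}" for i in range(40)]
        labels = {g: i // 10 for i, g in enumerate(ids)}
        vals = rng.normal(0, 0.05, (40, 40))
        for i in range(40):
            for j in range(40):
                if labels[ids[i]] == labels[ids[j]]:
                    vals[i, j] += 0.5
        vals = (vals + vals.T) / 2
        mat = pd.DataFrame(vals, index=ids, columns=ids)
        within = within_community_values(labels, mat)
        control = resampled_control([10] * 4, ids, mat, n_boot=50, seed=2)
        assert control.mean() < within.mean()


class TestCompare:
    def test_identical_vectors_near_half(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=400)
        assert compare_distributions(v, v.copy()) == pytest.approx(0.5, abs=0.02)

    def test_direction(self):
        lo, hi = np.zeros(50), np.ones(50)
        assert compare_distributions(hi, lo) < 1e-6
        assert compare_distributions(lo, hi) > 0.999

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions(np.array([]), np.ones(3))


class TestPPI:
    def test_evidence_filter(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text(
            "g1\tg2\tTwo-Hybrid\n"
            "g3\tg4\tDosage Rescue\n"
            "g5\tg6\tAffinity Capture-MS\n"
            "g7\tg7\tTwo-Hybrid\n"  # self loop dropped
        )
        pairs = load_ppi(p)
        assert pairs == {frozenset(("g1", "g2")), frozenset(("g5", "g6"))}

    def test_planted_density_detected(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(60)]
        labels = {g: i // 15 for i, g in enumerate(ids)}
        pairs = set()
        for i in range(60):
            for j in range(i + 1, 60):
                same = labels[ids[i]] == labels[ids[j]]
                if rng.random() < (0.25 if same else 0.05):  # 5x background
                    pairs.add(frozenset((ids[i], ids[j])))
        res = ppi_count_enrichment(labels, pairs, n_boot=200, seed=0)
        assert res.p_value < 0.01

    def test_disjoint_ppi_gives_p_near_one(self):
        labels = {f"g{i}": i // 3 for i in range(9)}
        pairs = {frozenset(("x1", "x2"))}
        with pytest.warns(UserWarning, match="no PPI overlap"):
            res = ppi_count_enrichment(labels, pairs, n_boot=50, seed=0)
        assert np.isnan(res.p_value)

    def test_zero_observed_within_scores_one(self):
        labels = {f"g{i}": i // 3 for i in range(9)}
        # interactions only across communities
        pairs = {frozenset(("g0", "g3")), frozenset(("g1", "g6"))}
        res = ppi_count_enrichment(labels, pairs, n_boot=100, seed=0)
        assert res.p_value == pytest.approx(1.0)


class TestHubFisher:
    def test_exclusive_term_matches_hypergeometric_tail(self):
        hubs = {f"h{i}" for i in range(5)}
        others = {f"o{i}" for i in range(15)}
        annotations = [(g, "GO:X") for g in hubs]
        table = hub_go_fisher(hubs, hubs | others, annotations)
        row = table[table["term"] == "GO:X"].iloc[0]
        # oracle: exact hypergeometric tail P(all 5 of 5 drawn are hubs)
        oracle = stats.hypergeom.sf(4, 20, 5, 5)
        assert row["p"] == pytest.approx(oracle)

    def test_proportional_term_not_enriched(self):
        hubs = {f"h{i}" for i in range(5)}
        others = {f"o{i}" for i in range(15)}
        annotations = [(g, "GO:Y") for g in list(hubs)[:1] + list(others)[:3]]
        table = hub_go_fisher(hubs, hubs | others, annotations)
        assert table.iloc[0]["p"] > 0.5

    def test_planted_regulator_ranked_first(self):
        rng = np.random.default_rng(7)
        hubs = {f"h{i}" for i in range(8)}
        others = {f"o{i}" for i in range(40)}
        universe = hubs | others
        annotations = [(g, "GO:REG") for g in hubs]
        for g in sorted(universe):
            for t in ("GO:A", "GO:B", "GO:C"):
                if rng.random() < 0.3:
                    annotations.append((g, t))
        table = hub_go_fisher(hubs, universe, annotations)
        assert table.iloc[0]["term"] == "GO:REG"

    def test_universe_must_contain_hubs(self):
        with pytest.raises(ValueError):
            hub_go_fisher({"a"}, {"b"}, [])


class TestLevel1Sharing:
    def b_matrix(self, rows):
        ids = sorted(rows)
        cols = [f"T{i}" for i in range(len(next(iter(rows.values()))))]
        vals = np.array([rows[g] for g in ids], dtype=float)
        return WeightedBiadjacency(row_ids=ids, col_ids=cols, values=vals, level=1)

    def test_universal_sharing_gives_null_table(self):
        B = self.b_matrix({f"g{i}": [1, 1, 1] for i in range(6)})
        res = level1_sharing_chisq({f"g{i}": i // 3 for i in range(6)}, B)
        assert res.frac_same_within == 1.0
        assert res.frac_same_overall == 1.0
        assert res.chi_sq == pytest.approx(0.0)

    def test_hand_computed_table(self):
        rows = {
            "a": [1, 1, 0, 0], "b": [1, 1, 0, 0],
            "c": [0, 0, 1, 0], "d": [0, 0, 1, 1],
        }
        B = self.b_matrix(rows)
        labels = {"a": 0, "b": 0, "c": 1, "d": 1}
        res = level1_sharing_chisq(labels, B)
        # shared counts: ab=2, cd=1, all cross pairs 0
        within = np.array([0, 1, 1, 0])
        alls = np.array([4, 1, 1, 0])
        expected = stats.chi2_contingency(
            np.vstack([within, alls])[:, :3], correction=False
        )
        assert res.chi_sq == pytest.approx(expected.statistic)
        assert res.frac_same_within == pytest.approx(1.0)
        assert res.frac_same_overall == pytest.approx(2 / 6)

    def test_planted_modules_share_more(self, study_bundle, study_result):
        res = study_result.contingency
        assert res.frac_same_within > res.frac_same_overall
        assert res.p < 1e-3
        assert res.dof == 3

    def test_no_partition_rejected(self):
        B = self.b_matrix({"a": [1], "b": [1]})
        with pytest.raises(ValueError):
            level1_sharing_chisq({}, B)


def test_metric_enrichment_on_correlated_blocks():
    rng = np.random.default_rng(5)
    ids = [f"g{i}" for i in range(30)]
    labels = {g: i // 10 for i, g in enumerate(ids)}
    base = {m: rng.normal(size=80) for m in range(3)}
    data = pd.DataFrame(
        [0.8 * base[labels[g]] + 0.6 * rng.normal(size=80) for g in ids],
        index=ids,
    )
    mat = correlation_matrix(data)
    res = metric_enrichment(labels, mat, n_boot=100, seed=0)
    assert res.p_value < 1e-4
    assert res.within_mean > res.control_mean
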