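"""Enrichment, reference similarity, markers, TF differential expression."""

import math

import numpy as np
import pandas as pd
import pytest

from emat.characterize import (
    adjacent_similarity_tests,
    hypergeometric_enrichment,
    jaccard_concordance,
    marker_profile,
    per_gene_survival_association,
    signature_overlap,
    similarity_to_reference,
    tf_differential_expression,
    top_tfs_per_cluster,
)
from emat.preprocess import ExpressionMatrix
from emat.signature import GeneSignature, SignatureEntry
from emat.survival import SurvivalTable
from .conftest import make_blobs_matrix


def tail_p(N, K, n, k):
    """Exhaustive hypergeometric tail by direct combinatorial enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestHypergeometricEnrichment:
    def _pvalue(self, N, K, n, k):
        samples = [f"s{i}" for i in range(N)]
        cl = pd.Series(["in"] * n + ["out"] * (N - n), index=samples)
        cat = pd.Series("other", index=samples, dtype=object)
        cat.iloc[:k] = "g"
        cat.iloc[n : n + (K - k)] = "g"
        return hypergeometric_enrichment(cl, cat).pvalues.loc["in", "g"]

    def test_worked_example(self):
        # N=20, K=10, n=5, k=4 -> (C(10,4)C(10,1) + C(10,5)) / C(20,5)
        expected = (math.comb(10, 4) * math.comb(10, 1) + math.comb(10, 5)) / math.comb(20, 5)
        assert expected == pytest.approx(0.1517, abs=5e-5)
        assert self._pvalue(20, 10, 5, 4) == pytest.approx(expected)

    def test_zero_overlap_is_certain(self):
        assert self._pvalue(12, 4, 3, 0) == pytest.approx(1.0)

    def test_category_equals_universe_is_certain(self):
        samples = [f"s{i}" for i in range(10)]
        cl = pd.Series(["a"] * 4 + ["b"] * 6, index=samples)
        cat = pd.Series(["g"] * 10, index=samples)
        assert (hypergeometric_enrichment(cl, cat).pvalues == 1.0).all().all()

    def test_missing_categories_excluded_from_universe(self):
        samples = [f"s{i}" for i in range(8)]
        cl = pd.Series(["a"] * 4 + ["b"] * 4, index=samples)
        cat = pd.Series(["g", "g", None, None, "h", "h", None, None], index=samples)
        enr = hypergeometric_enrichment(cl, cat)
        assert enr.counts[("a", "g")] == (4, 2, 2, 2)

    def test_tail_complement_identity(self):
        # P(X >= k) + P(X <= k-1) = 1, both tails enumerated independently
        for N, K, n, k in [(10, 4, 5, 2), (25, 12, 8, 5), (15, 7, 7, 1)]:
            upper = tail_p(N, K, n, k)
            lower = sum(
                math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(max(0, n - (N - K)), k)
            ) / math.comb(N, n)
            assert upper + lower == pytest.approx(1.0)
            assert self._pvalue(N, K, n, k) == pytest.approx(upper)

    def test_empty_universe_rejected(self):
        s = pd.Series(dtype=object)
        with pytest.raises(ValueError, match="empty"):
            hypergeometric_enrichment(s, s)


class TestSimilarityToReference:
    def test_two_sample_cohort_hits_endpoints(self, rng):
        values = pd.DataFrame(rng.normal(size=(10, 2)), columns=["s1", "s2"])
        m = ExpressionMatrix(values, scale="zscore")
        ref = pd.Series(rng.normal(size=10), index=values.index)
        sim = similarity_to_reference(m, ref)
        assert sorted(sim["scaled"]) == [0.0, 1.0]

    def test_sample_equal_to_reference_is_max(self, rng):
        values = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        ref = values["c"].copy()
        m = ExpressionMatrix(values, scale="zscore")
        sim = similarity_to_reference(m, ref)
        assert sim.loc["c", "raw"] == pytest.approx(1.0)
        assert sim.loc["c", "scaled"] == pytest.approx(1.0)

    def test_invariant_to_monotone_transform_of_reference(self, rng):
        values = pd.DataFrame(rng.normal(size=(15, 5)))
        values.columns = [f"s{i}" for i in range(5)]
        m = ExpressionMatrix(values, scale="zscore")
        ref = pd.Series(rng.normal(size=15), index=values.index)
        a = similarity_to_reference(m, ref)["raw"]
        b = similarity_to_reference(m, np.exp(2 * ref) + 5)["raw"]
        pd.testing.assert_series_equal(a, b)

    def test_constant_similarity_falls_back_to_half(self):
        values = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [2.0, 4.0, 6.0]}, index=["g1", "g2", "g3"]
        )
        m = ExpressionMatrix(values, scale="zscore")
        ref = pd.Series([1.0, 2.0, 3.0], index=values.index)
        with pytest.warns(UserWarning, match="equally similar"):
            sim = similarity_to_reference(m, ref)
        assert (sim["scaled"] == 0.5).all()

    def test_gradient_reference_orders_clusters(self):
        from emat.simulate import generate_reference_profile

        m, truth = make_blobs_matrix(40, 60, K=4, separation=5.0, seed=13)
        centroids = pd.DataFrame(
            {k: m.values.loc[:, truth == k].mean(axis=1) for k in range(1, 5)}
        )
        ref = generate_reference_profile(centroids, [0.0, 0.4, 0.8, 1.2])
        sim = similarity_to_reference(m, ref)
        names = truth.map({1: "EMAT1", 2: "EMAT2", 3: "EMAT3", 4: "EMAT4"})
        means = sim["scaled"].groupby(names).mean()
        assert list(means.index) == sorted(means.index)
        assert means.is_monotonic_increasing
        tests = adjacent_similarity_tests(sim, names)
        assert (tests["p"] < 1e-3).all()


class TestMarkerProfile:
    def test_planted_shift_ranks_first_and_significant(self, rng):
        m, truth = make_blobs_matrix(50, 10, K=4, separation=0.0, seed=17)
        vim = pd.Series(rng.normal(0, 1, m.n_samples), index=m.values.columns)
        vim[truth == 3] += 3.0
        values = m.values.copy()
        values.loc["VIM"] = vim
        m2 = ExpressionMatrix(values, scale="zscore")
        table, missing = marker_profile(m2, truth, markers=("VIM", "NOPE"))
        assert missing == ["NOPE"]
        row = table[(table["marker"] == "VIM") & (table["cluster"] == 3)].iloc[0]
        assert row["rank"] == 1
        assert row["p"] < 1e-6

    def test_t_statistic_matches_hand_formula(self):
        x_in = np.array([3.0, 4.0, 5.0])
        x_out = np.array([1.0, 1.5, 2.0, 2.5])
        values = pd.DataFrame([np.concatenate([x_in, x_out])], index=["CDH1"])
        values.columns = [f"s{i}" for i in range(7)]
        m = ExpressionMatrix(values, scale="zscore")
        labels = pd.Series([1, 1, 1, 2, 2, 2, 2], index=values.columns)
        table, _ = marker_profile(m, labels, markers=("CDH1",))
        # Welch p computed by hand from t = (m1-m2)/sqrt(v1/n1 + v2/n2)
        from scipy.stats import ttest_ind

        expected = ttest_ind(x_in, x_out, equal_var=False).pvalue
        got = table[(table["marker"] == "CDH1") & (table["cluster"] == 1)].iloc[0]["p"]
        assert got == pytest.approx(expected)


class TestPerGeneSurvival:
    def test_planted_prognostic_gene_ranks_top(self, rng):
        n = 500
        samples = [f"s{i}" for i in range(n)]
        hit = rng.normal(size=n)
        noise = rng.normal(size=(9, n))
        values = pd.DataFrame(
            np.vstack([hit, noise]),
            index=["hit"] + [f"bg{i}" for i in range(9)],
            columns=samples,
        )
        rates = 0.02 * np.exp(0.8 * hit)
        times = rng.exponential(1 / rates)
        surv = SurvivalTable.from_arrays(samples, times, np.ones(n, dtype=int))
        m = ExpressionMatrix(values, scale="zscore")
        out = per_gene_survival_association(m, surv)
        assert out.index[0] == "hit"
        assert out.loc["hit", "p"] < 0.01

    def test_permuted_survival_controls_false_positives(self, rng):
        n = 300
        samples = [f"s{i}" for i in range(n)]
        values = pd.DataFrame(
            rng.normal(size=(100, n)),
            index=[f"g{i}" for i in range(100)], columns=samples,
        )
        surv = SurvivalTable.from_arrays(
            samples, rng.exponential(50, n), rng.integers(0, 2, n)
        )
        out = per_gene_survival_association(ExpressionMatrix(values, scale="zscore"), surv)
        assert out["significant"].mean() <= 0.05  # ~1% expected at p < 0.01

    def test_constant_gene_excluded_with_warning(self, rng):
        samples = [f"s{i}" for i in range(30)]
        values = pd.DataFrame(
            {"flat": np.ones(30), "ok": rng.normal(size=30)}, index=samples
        ).T
        surv = SurvivalTable.from_arrays(
            samples, rng.exponential(50, 30), np.ones(30, dtype=int)
        )
        with pytest.warns(UserWarning, match="constant"):
            out = per_gene_survival_association(ExpressionMatrix(values, scale="zscore"), surv)
        assert list(out.index) == ["ok"]


class TestTFDifferentialExpression:
    def test_planted_tf_recovered_as_top(self, rng):
        m, truth = make_blobs_matrix(40, 30, K=4, separation=0.0, seed=19)
        values = m.values.copy()
        tf = pd.Series(rng.normal(size=m.n_samples), index=values.columns)
        tf[truth == 3] += 2.5
        values.loc["TFX"] = tf
        de = tf_differential_expression(
            ExpressionMatrix(values, scale="zscore"), truth,
            tf_list=["TFX"] + [f"g{i}" for i in range(30)],
        )
        top = top_tfs_per_cluster(de)
        row = top[(top["cluster"] == 3) & (top["direction"] == "over")].iloc[0]
        assert row["tf"] == "TFX"

    def test_bonferroni_is_min_one_p_times_m(self, rng):
        m, truth = make_blobs_matrix(20, 8, K=2, separation=0.0, seed=23)
        de = tf_differential_expression(m, truth, tf_list=list(m.values.index))
        n_tests = len(de)
        np.testing.assert_allclose(
            de["p_bonferroni"], np.minimum(1.0, de["p_raw"] * n_tests)
        )

    def test_null_family_wise_error_controlled(self, rng):
        hits = 0
        for seed in range(5):
            m, truth = make_blobs_matrix(30, 200, K=4, separation=0.0, seed=seed)
            de = tf_differential_expression(m, truth, tf_list=list(m.values.index))
            hits += int(de["significant"].any())
        assert hits <= 1  # family-wise alpha 0.01 over 5 null families

    def test_singleton_cluster_skipped(self, rng):
        values = pd.DataFrame(rng.normal(size=(5, 5)),
                              columns=[f"s{i}" for i in range(5)])
        labels = pd.Series([1, 1, 1, 1, 2], index=values.columns)
        with pytest.warns(UserWarning, match="fewer than 2"):
            de = tf_differential_expression(
                ExpressionMatrix(values, scale="zscore"), labels,
                tf_list=list(values.index),
            )
        assert set(de["cluster"]) == {1}


class TestJaccardConcordance:
    def test_identical_labelings_diagonal_ones(self):
        labels = pd.Series(["a", "a", "b", "b", "c"], index=list("vwxyz"))
        J, matching, mean = jaccard_concordance(labels, labels)
        assert mean == pytest.approx(1.0)
        assert all(matching[c] == c for c in matching)

    def test_renamed_labeling_still_perfect(self):
        a = pd.Series(["a", "a", "b", "b"], index=list("wxyz"))
        b = a.map({"a": "q", "b": "r"})
        _, matching, mean = jaccard_concordance(a, b)
        assert mean == pytest.approx(1.0)
        assert matching == {"a": "q", "b": "r"}

    def test_hand_built_overlap_case(self):
        # A = {1:{s1,s2,s3}, 2:{s4,s5,s6}}, B = {x:{s1,s2,s4}, y:{s3,s5,s6}}
        a = pd.Series([1, 1, 1, 2, 2, 2], index=[f"s{i}" for i in range(1, 7)])
        b = pd.Series(["x", "x", "y", "x", "y", "y"], index=a.index)
        J, matching, mean = jaccard_concordance(a, b)
        assert J.loc[1, "x"] == pytest.approx(2 / 4)
        assert J.loc[1, "y"] == pytest.approx(1 / 5)
        assert J.loc[2, "x"] == pytest.approx(1 / 5)
        assert J.loc[2, "y"] == pytest.approx(2 / 4)
        assert matching == {1: "x", 2: "y"}
        assert mean == pytest.approx(0.5)

    def test_disjoint_universes_rejected(self):
        a = pd.Series([1], index=["s1"])
        b = pd.Series([1], index=["s2"])
        with pytest.raises(ValueError, match="share no samples"):
            jaccard_concordance(a, b)


def test_signature_overlap_utility():
    a = GeneSignature([SignatureEntry(g) for g in ["CDH1", "ELMO3", "RPS6KA1", "ZZZ"]])
    b = GeneSignature([SignatureEntry(g, "MAT") for g in ["CDH1", "ELMO3", "RPS6KA1", "AAA"]])
    assert signature_overlap(a, b) == ["CDH1", "ELMO3", "RPS6KA1"]
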