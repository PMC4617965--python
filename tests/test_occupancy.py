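import math
from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ripnet.diffbind import BindingCall
from ripnet.occupancy import (
    build_binding_matrix,
    class_rank_sum,
    hot_test,
    max_occupancy_test,
    median_rank_curve,
    pairwise_overlap,
    poisson_binomial_pmf,
    poisson_binomial_tail,
    rank_list_enrichment,
    set_enrichment,
)


def call(gene, idr=0.01, passed=True):
    return BindingCall(gene, "B", idr, 2.0, passed)


def matrix_from_sets(sets):
    return build_binding_matrix(
        {bait: [call(g) for g in genes] for bait, genes in sets.items()}
    )


def brute_force_tail(p, t):
    """O(2^n) enumeration of P(X >= t)."""
    total = 0.0
    for outcome in product([0, 1], repeat=len(p)):
        if sum(outcome) >= t:
            prob = 1.0
            for x, pj in zip(outcome, p):
                prob *= pj if x else 1 - pj
            total += prob
    return total


class TestBindingMatrix:
    def test_shared_target_column_sums(self):
        m = matrix_from_sets({"b1": ["g1", "g2"], "b2": ["g2", "g3"]})
        assert len(m.genes) == 3
        assert list(m.bait_target_counts) == [2, 2]

    def test_empty_calls(self):
        m = matrix_from_sets({"b1": [], "b2": []})
        assert m.genes == []

    def test_failed_calls_excluded(self):
        m = build_binding_matrix({"b1": [call("g1"), call("g2", passed=False)]})
        assert m.genes == ["g1"]

    def test_duplicate_keeps_min_idr(self):
        m = build_binding_matrix({"b1": [call("g1", 0.05), call("g1", 0.001)]})
        assert m.strength.loc["g1", "b1"] == pytest.approx(3.0)

    def test_recovers_truth_occupancy(self, strong_bundle):
        from ripnet.diffbind import run_bait

        baits = strong_bundle.cfg.baits[:3]
        calls = {
            b: run_bait(strong_bundle.gene_counts, b)[2] for b in baits
        }
        m = build_binding_matrix(calls)
        for b in baits:
            truth = strong_bundle.truth.target_set(b)
            assert len(m.targets(b) & truth) / len(truth) > 0.7


class TestPoissonBinomial:
    def test_pmf_sums_to_one(self, rng):
        p = rng.random(30)
        assert poisson_binomial_pmf(p).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_tail(self):
        assert poisson_binomial_tail([0.0] * 5, 1) == 0.0

    def test_t_zero_is_one(self, rng):
        assert poisson_binomial_tail(rng.random(10), 0) == 1.0

    def test_equal_p_matches_binomial(self):
        q = poisson_binomial_tail([0.5] * 20, 10)
        assert abs(q - stats.binom.sf(9, 20, 0.5)) < 1e-12
        q = poisson_binomial_tail([0.13] * 15, 4)
        assert abs(q - stats.binom.sf(3, 15, 0.13)) < 1e-12

    @pytest.mark.parametrize("n,t", [(8, 3), (10, 5), (12, 7)])
    def test_matches_brute_force(self, n, t, rng):
        p = rng.random(n)
        assert poisson_binomial_tail(p, t) == pytest.approx(
            brute_force_tail(p, t), abs=1e-12
        )

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            poisson_binomial_tail([1.5], 0)

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25)
    )
    @settings(max_examples=50, deadline=None)
    def test_pmf_is_distribution(self, p):
        pmf = poisson_binomial_pmf(p)
        assert pmf.size == len(p) + 1
        assert (pmf >= -1e-15).all()
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=15),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_tail_monotone_in_t(self, p, data):
        t = data.draw(st.integers(1, len(p)))
        assert poisson_binomial_tail(p, t - 1) >= poisson_binomial_tail(p, t) - 1e-15


class TestHotTest:
    def test_threshold_ceil_half(self):
        sets = {f"b{i}": ["g1", f"x{i}"] for i in range(20)}
        m = matrix_from_sets(sets)
        assert hot_test(m).threshold == 10

    def test_planted_hot_recovered(self, strong_bundle):
        truth = strong_bundle.truth
        m = matrix_from_sets(
            {b: sorted(truth.target_set(b)) for b in truth.baits}
        )
        res = hot_test(m)
        recall = len(set(res.genes) & truth.hot_genes) / len(truth.hot_genes)
        assert recall >= 0.9
        assert res.fold > 10
        assert res.p_value < 1e-6

    def test_independence_fixture_calibrated(self):
        folds = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(400)]
            p = rng.uniform(0.2, 0.5, 12)
            sets = {
                f"b{j}": [g for g in genes if rng.random() < p[j]]
                for j in range(12)
            }
            res = hot_test(matrix_from_sets(sets))
            folds.append(res.fold)
        assert 0.5 <= np.median(folds) <= 2.0

    def test_all_zero_probabilities_error(self):
        with pytest.raises(ValueError):
            hot_test(matrix_from_sets({"b1": []}))


class TestMaxOccupancy:
    def test_q_zero(self):
        m = matrix_from_sets({f"b{i}": ["g1"] for i in range(3)})
        # m > observed support with p_j = 1 gives q > 0; use t beyond n
        assert max_occupancy_test(m, 3) >= 0

    def test_single_gene_p_equals_q(self):
        m = matrix_from_sets({"b1": ["g1"], "b2": ["g1"]})
        p = m.bait_target_counts.to_numpy() / 1
        q = poisson_binomial_tail(p, 2)
        assert max_occupancy_test(m, 2) == pytest.approx(q)

    def test_small_case_enumeration(self):
        # N=3 genes, 2 baits each with p=2/3 under the conditioned universe
        m = matrix_from_sets({"b1": ["g1", "g2"], "b2": ["g2", "g3"]})
        p = [2 / 3, 2 / 3]
        q = brute_force_tail(p, 2)
        want = 1 - (1 - q) ** 3
        assert max_occupancy_test(m, 2) == pytest.approx(want)

    def test_m_too_large(self):
        m = matrix_from_sets({"b1": ["g1"]})
        with pytest.raises(ValueError):
            max_occupancy_test(m, 5)


class TestPairwiseOverlap:
    def test_20_baits_190_pairs(self):
        sets = {f"b{i:02d}": [f"g{i}", "shared"] for i in range(20)}
        df, _ = pairwise_overlap(matrix_from_sets(sets), universe={
            *(f"g{i}" for i in range(20)), "shared"})
        assert len(df) == 190

    def test_identical_sets_extreme_p(self):
        universe = {f"g{i}" for i in range(10)}
        targets = [f"g{i}" for i in range(5)]
        df, _ = pairwise_overlap(
            matrix_from_sets({"b1": targets, "b2": targets}), universe
        )
        assert df["p_value"].iloc[0] == pytest.approx(1 / 252)

    def test_disjoint_sets_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        df, n_sig = pairwise_overlap(
            matrix_from_sets(
                {"b1": ["g0", "g1"], "b2": ["g5", "g6"]}
            ),
            universe,
        )
        assert df["p_value"].iloc[0] == pytest.approx(1.0)
        assert n_sig == 0

    def test_symmetry(self):
        universe = {f"g{i}" for i in range(30)}
        a = {"b1": ["g0", "g1", "g2"], "b2": ["g2", "g3"]}
        b = {"b2": ["g2", "g3"], "b1": ["g0", "g1", "g2"]}
        pa, _ = pairwise_overlap(matrix_from_sets(a), universe)
        pb, _ = pairwise_overlap(matrix_from_sets(b), universe)
        assert pa["p_value"].iloc[0] == pytest.approx(pb["p_value"].iloc[0])

    def test_single_bait_errors(self):
        with pytest.raises(ValueError):
            pairwise_overlap(matrix_from_sets({"b1": ["g1"]}), {"g1"})


class TestSetEnrichment:
    def test_query_equals_universe(self):
        u = {f"g{i}" for i in range(10)}
        res = set_enrichment(u, u, u)
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_enumeration_oracle_u12(self):
        universe = set(range(12))
        ref = set(range(6))
        query = {0, 1, 2, 3}
        k = len(query & ref)
        # exhaustive: P(overlap >= k) over all C(12,4) draws of size 4
        hits = total = 0
        for draw in combinations(universe, 4):
            total += 1
            if len(set(draw) & ref) >= k:
                hits += 1
        res = set_enrichment(query, ref, universe)
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_below_expectation_direction(self):
        universe = {f"g{i}" for i in range(100)}
        ref = {f"g{i}" for i in range(50)}
        query = {"g60", "g61", "g62", "g63"}  # overlap 0, expectation 2
        assert set_enrichment(query, ref, universe).p_value > 0.5

    def test_binomial_variant(self):
        universe = {f"g{i}" for i in range(100)}
        ref = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(10)}
        res = set_enrichment(query, ref, universe, test="binomial")
        assert res.p_value == pytest.approx(stats.binom.sf(9, 10, 0.2))

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            set_enrichment(set(), set(), set())


class TestClassRankSum:
    def test_identical_values_p_one(self):
        stat = pd.Series([2.0] * 6)
        labels = pd.Series(["a"] * 3 + ["b"] * 3)
        df = class_rank_sum(stat, labels)
        assert (df["p_value"] == 1.0).all()

    def test_exact_small_groups(self):
        stat = pd.Series([1, 2, 3, 4, 5, 6], dtype=float)
        labels = pd.Series(["a"] * 3 + ["b"] * 3)
        df = class_rank_sum(stat, labels)
        assert df.loc[df["class"] == "a", "p_value"].iloc[0] == pytest.approx(0.1)

    def test_small_class_flagged(self):
        stat = pd.Series([1.0, 2.0, 3.0, 4.0])
        labels = pd.Series(["a", "b", "b", "b"])
        df = class_rank_sum(stat, labels)
        assert not df.loc[df["class"] == "a", "defined"].iloc[0]

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(400):
            stat = pd.Series(rng.standard_normal(14))
            labels = pd.Series(["a"] * 7 + ["b"] * 7)
            df = class_rank_sum(stat, labels)
            pvals.append(df["p_value"].iloc[0])
        assert (np.array(pvals) < 0.05).mean() == pytest.approx(0.05, abs=0.035)


class TestRankListEnrichment:
    def _matrix(self, n_targets, rng):
        calls = [
            call(f"g{i:03d}", idr=10 ** -rng.uniform(1.1, 8)) for i in range(n_targets)
        ]
        return build_binding_matrix({"b1": calls})

    def test_disjoint_gene_set_flat(self, rng):
        m = self._matrix(150, rng)
        universe = set(m.genes) | {"x1", "x2"}
        df = rank_list_enrichment(m, "b1", {"x1", "x2"}, universe)
        assert np.allclose(df["neg_log10_p"], 0.0)

    def test_binning_rule_250(self, rng):
        m = self._matrix(250, rng)
        df = rank_list_enrichment(m, "b1", set(), set(m.genes))
        assert list(df["n"]) == [100, 100, 50]

    def test_head_enrichment_detected(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genes = [f"g{i:03d}" for i in range(300)]
            idrs = np.sort(10 ** -rng.uniform(1.1, 9, 300))[::-1]
            calls = [call(g, idr=idrs[i]) for i, g in enumerate(genes)]
            m = build_binding_matrix({"b1": calls})
            # gene set concentrated at the strong head of the ranking
            strong = sorted(
                m.strength["b1"].sort_values(ascending=False).index[:120]
            )
            gene_set = set(rng.choice(strong, 60, replace=False))
            gene_set |= set(rng.choice(genes, 10, replace=False))
            df = rank_list_enrichment(m, "b1", gene_set, set(genes))
            if df["neg_log10_p"].iloc[0] > df["neg_log10_p"].iloc[-1]:
                wins += 1
        assert wins >= 18

    def test_median_curve_shape(self, rng):
        calls = {
            b: [call(f"g{i:03d}", idr=10 ** -rng.uniform(1.1, 6)) for i in range(120)]
            for b in ("b1", "b2", "b3")
        }
        m = build_binding_matrix(calls)
        df = median_rank_curve(m, {"g001", "g002"}, set(m.genes))
        assert "median_neg_log10_p" in df
        assert len(df) == 2  # 120 targets -> bins of 100 and 20
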