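"""Stratified matching, one-sided KS/Fisher tests, repetitions and BH-FDR."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from mirmatch.matched import (
    MatchedSample,
    TestConfig,
    bh_adjust,
    fisher_one_sided,
    ks_one_sided,
    make_bins,
    pairwise_combination_tests,
    run_matched_test,
    stratified_match,
)


class TestMakeBins:
    def test_final_bin_closed_at_maximum(self):
        assert make_bins([450], [100], 200) == [(0, 200), (200, 400), (400, 450)]

    def test_exact_multiple_has_no_empty_trailing_bin(self):
        assert make_bins([400], [100], 200) == [(0, 200), (200, 400)]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_bins([100], [100], 0)
        with pytest.raises(ValueError):
            make_bins([], [100], 200)
        with pytest.raises(ValueError):
            make_bins([100], [-5], 200)


class TestStratifiedMatch:
    def test_min_rule_within_one_bin(self, rng):
        ms = stratified_match([100, 150], [120, 130, 140], 200, rng)
        assert ms.n_matched == 2
        assert len(ms.target_idx) == len(ms.nontarget_idx) == 2

    def test_disjoint_bins_give_empty_sample(self, rng):
        ms = stratified_match([100], [500], 200, rng)
        assert ms.n_matched == 0

    def test_equal_groups_pass_through_in_order(self, rng):
        ms = stratified_match([50, 250], [80, 280], 200, rng)
        assert list(ms.target_idx) == [0, 1]
        assert list(ms.nontarget_idx) == [0, 1]

    def test_balance_equals_sum_of_bin_minima(self, rng):
        # matched totals always equal sum over bins of min(counts)
        for _ in range(200):
            t = rng.integers(1, 2000, size=rng.integers(1, 60))
            n = rng.integers(1, 2000, size=rng.integers(1, 60))
            ms = stratified_match(t, n, 200, rng)
            max_len = max(t.max(), n.max())
            nbins = max(1, math.ceil(max_len / 200))
            expected = sum(
                min(((t // 200).clip(max=nbins - 1) == b).sum(),
                    ((n // 200).clip(max=nbins - 1) == b).sum())
                for b in range(nbins)
                if ((t // 200).clip(max=nbins - 1) == b).any()
                and ((n // 200).clip(max=nbins - 1) == b).any()
            )
            assert len(ms.target_idx) == len(ms.nontarget_idx) == expected

    def test_unbalanced_vectors_rejected(self):
        with pytest.raises(AssertionError):
            MatchedSample(np.array([1, 2]), np.array([1]))


class TestKSOneSided:
    def test_identical_samples(self):
        d, p = ks_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater")
        assert d == 0.0 and p == 1.0

    def test_fully_separated_samples(self):
        d, p = ks_one_sided([1, 2, 3], [4, 5, 6], "greater")
        assert d == 1.0
        assert p == pytest.approx(math.exp(-3.0))

    def test_less_alternative_mirrors_greater(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=25)
        d1, p1 = ks_one_sided(x, y, "less")
        d2, p2 = ks_one_sided(y, x, "greater")
        assert d1 == pytest.approx(d2) and p1 == pytest.approx(p2)

    def test_statistic_matches_scipy(self, rng):
        # independent route: scipy's one-sided two-sample statistic
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 30))
            y = rng.normal(0.3, size=rng.integers(2, 30))
            d, _ = ks_one_sided(x, y, "greater")
            ref = stats.ks_2samp(x, y, alternative="greater")
            assert d == pytest.approx(ref.statistic)

    def test_exact_matches_enumeration_and_asymptotic_close(self, rng):
        for _ in range(20):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            d, p_asymp = ks_one_sided(x, y, "greater")
            _, p_exact = ks_one_sided(x, y, "greater", method="exact")
            # exact p is a multiple of 1/C(8,4)
            assert (p_exact * comb(8, 4, exact=True)) == pytest.approx(
                round(p_exact * comb(8, 4, exact=True))
            )
            assert p_asymp >= p_exact - 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_one_sided([], [1.0], "greater")
        with pytest.raises(ValueError):
            ks_one_sided([1.0], [1.0], "two-sided")


def fisher_tail_oracle(a, b, c, d):
    """Hypergeometric upper-tail sum by direct enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    total = comb(n, c1, exact=True)
    p = 0
    for k in range(a, min(r1, c1) + 1):
        if c1 - k <= r2:
            p += comb(r1, k, exact=True) * comb(r2, c1 - k, exact=True)
    return p / total


class TestFisherOneSided:
    def test_zero_top_left_is_entire_tail(self):
        assert fisher_one_sided([[0, 3], [2, 1]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_one_sided([[2, 0], [0, 2]]) == pytest.approx(1 / 6)

    def test_matches_enumeration_oracle(self):
        assert fisher_one_sided([[3, 1], [1, 5]]) == pytest.approx(
            fisher_tail_oracle(3, 1, 1, 5)
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided([[1, -1], [0, 2]])


class TestBHAdjust:
    def test_step_up_formula(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_is_identity(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_nan_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # family size m=2: q = (0.02, 0.04)
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRunMatchedTest:
    def _inputs(self, rng, n=400):
        lengths = rng.integers(30, 2000, size=n)
        mask = rng.random(n) < 0.3
        log2fc = rng.normal(size=n)
        return mask, lengths, log2fc

    def test_single_rep_deterministic(self, rng):
        mask, lengths, log2fc = self._inputs(rng)
        cfg = TestConfig(n_reps=1, rng_seed=42)
        r1 = run_matched_test("m", "ks", "up", mask, lengths, log2fc=log2fc, cfg=cfg)
        r2 = run_matched_test("m", "ks", "up", mask, lengths, log2fc=log2fc, cfg=cfg)
        assert r1.rep_pvalues[0] == r2.rep_pvalues[0]
        assert not np.isnan(r1.mean_p)

    def test_down_direction_uses_less_alternative(self, rng):
        mask, lengths, log2fc = self._inputs(rng)
        r = run_matched_test(
            "m", "ks", "down", mask, lengths, log2fc=log2fc,
            cfg=TestConfig(n_reps=2, rng_seed=0),
        )
        assert r.alternative == "less"

    def test_no_targets_yields_na_not_exception(self, rng):
        _, lengths, log2fc = self._inputs(rng)
        r = run_matched_test(
            "m", "ks", "up", np.zeros(len(lengths), dtype=bool), lengths,
            log2fc=log2fc, cfg=TestConfig(n_reps=2),
        )
        assert r.is_na and np.isnan(r.mean_p)

    def test_disjoint_length_bins_yield_na(self):
        lengths = np.array([100, 100, 900, 900])
        mask = np.array([True, True, False, False])
        r = run_matched_test(
            "m", "ks", "up", mask, lengths, log2fc=np.ones(4),
            cfg=TestConfig(n_reps=2),
        )
        assert r.is_na

    def test_fisher_detects_planted_enrichment(self, rng):
        n = 600
        lengths = rng.integers(30, 1000, size=n)
        mask = rng.random(n) < 0.4
        opp = np.zeros(n, dtype=bool)
        # opposite-direction DE concentrated in targets
        opp[mask] = rng.random(mask.sum()) < 0.3
        opp[~mask] = rng.random((~mask).sum()) < 0.05
        r = run_matched_test(
            "m", "fisher", "up", mask, lengths, opposite_de_mask=opp,
            cfg=TestConfig(n_reps=20, rng_seed=1),
        )
        assert r.mean_p < 0.01

    def test_repression_detected_by_ks(self, rng):
        mask, lengths, log2fc = self._inputs(rng, n=800)
        log2fc[mask] -= 1.0
        r = run_matched_test(
            "m", "ks", "up", mask, lengths, log2fc=log2fc,
            cfg=TestConfig(n_reps=20, rng_seed=2),
        )
        assert r.mean_p < 1e-6
        assert r.rejection_fraction() == 1.0


class TestPairwiseCombinations:
    GENES = [f"g{i}" for i in range(300)]

    def _setup(self, rng):
        lengths = rng.integers(30, 1500, size=len(self.GENES))
        log2fc = rng.normal(size=len(self.GENES))
        return lengths, log2fc

    def test_disjoint_target_sets_give_na(self, rng):
        lengths, log2fc = self._setup(rng)
        res = pairwise_combination_tests(
            {"a": "up", "b": "up"},
            {"a": set(self.GENES[:50]), "b": set(self.GENES[50:100])},
            self.GENES, lengths, log2fc=log2fc,
            cfg=TestConfig(n_reps=2),
        )
        assert len(res) == 1 and res[0].is_na

    def test_identical_target_sets_equal_single_mirna_result(self, rng):
        lengths, log2fc = self._setup(rng)
        shared = set(self.GENES[:80])
        cfg = TestConfig(n_reps=5, rng_seed=3)
        (pair,) = pairwise_combination_tests(
            {"a": "up", "b": "up"}, {"a": shared, "b": shared},
            self.GENES, lengths, log2fc=log2fc, cfg=cfg,
        )
        mask = np.array([g in shared for g in self.GENES])
        single = run_matched_test(
            "a", "ks", "up", mask, lengths, log2fc=log2fc, cfg=cfg
        )
        np.testing.assert_allclose(pair.rep_pvalues, single.rep_pvalues)

    def test_three_same_direction_mirnas_give_three_pairs(self, rng):
        lengths, log2fc = self._setup(rng)
        sets = {m: set(self.GENES[:100]) for m in ("a", "b", "c")}
        res = pairwise_combination_tests(
            {m: "down" for m in sets}, sets, self.GENES, lengths,
            log2fc=log2fc, cfg=TestConfig(n_reps=1),
        )
        assert len(res) == 3
        assert {r.test_id for r in res} == {"a+b", "a+c", "b+c"}

    def test_fewer_than_two_same_direction_is_empty(self, rng):
        lengths, log2fc = self._setup(rng)
        res = pairwise_combination_tests(
            {"a": "up", "b": "down"}, {"a": set(), "b": set()},
            self.GENES, lengths, log2fc=log2fc, cfg=TestConfig(n_reps=1),
        )
        assert res == []
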