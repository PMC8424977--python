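"""Unit and property tests for the core maximum-rank procedure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_mfdr, brute_mse_profile, random_max_ranks
from marrms.marr import (
    MaxRankStats,
    PairedRanks,
    assign_ranks,
    empirical_survival,
    estimate_pi1,
    expected_false_discoveries,
    ideal_survival,
    marr_pair,
    max_rank,
    mfdr_curve,
    select_threshold,
)
from marrms.simulate import simulate_ideal_ranks


class TestAssignRanks:
    def test_strict_ordering_descending(self):
        assert assign_ranks([3.0, 1.0, 2.0], tie_seed=0).tolist() == [1, 3, 2]
        assert assign_ranks([7.5], tie_seed=0).tolist() == [1]

    def test_missing_value_error_names_index(self):
        with pytest.raises(ValueError, match="index 2"):
            assign_ranks([1.0, 2.0, np.nan], tie_seed=0)
        with pytest.raises(ValueError, match="index 0"):
            assign_ranks([np.inf, 2.0], tie_seed=0)

    def test_deterministic_given_seed(self):
        v = [5.0, 5.0, 1.0, 5.0]
        a = assign_ranks(v, tie_seed=123)
        b = assign_ranks(v, tie_seed=123)
        assert np.array_equal(a, b)

    def test_tie_breaking_uniform_over_seeds(self):
        # (5, 5, 1): the two admissible permutations (1,2,3) and (2,1,3)
        # should each appear with empirical frequency ~ 1/2.
        hits = 0
        n = 10_000
        for seed in range(n):
            r = assign_ranks([5.0, 5.0, 1.0], tie_seed=seed)
            assert r[2] == 3
            hits += r[0] == 1
        freq = hits / n
        assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(n)

    @given(
        st.lists(
            st.floats(-1e6, 1e6).map(lambda v: round(v, 1)),
            min_size=1,
            max_size=40,
        ),
        st.integers(0, 2**31 - 1),
    )
    @settings(derandomize=True, max_examples=60)
    def test_always_a_permutation(self, values, seed):
        r = assign_ranks(values, tie_seed=seed)
        assert sorted(r) == list(range(1, len(values) + 1))
        # rank 1 goes to (one of) the largest values
        assert values[int(np.argmin(r))] == max(values)


class TestMaxRank:
    def test_elementwise_maximum(self):
        pair = PairedRanks(ranks_a=[1, 2, 3], ranks_b=[2, 1, 3])
        assert max_rank(pair).max_rank.tolist() == [2, 2, 3]

    def test_identical_permutations_are_identity(self):
        perm = np.random.default_rng(1).permutation(20) + 1
        stats = max_rank(PairedRanks(ranks_a=perm, ranks_b=perm))
        assert np.array_equal(stats.max_rank, perm)

    def test_matches_brute_force_on_random_permutations(self):
        rng = np.random.default_rng(7)
        a, b = rng.permutation(50) + 1, rng.permutation(50) + 1
        stats = max_rank(PairedRanks(ranks_a=a, ranks_b=b))
        expected = [max(x, y) for x, y in zip(a, b)]
        assert stats.max_rank.tolist() == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            PairedRanks(ranks_a=[1, 2, 3], ranks_b=[1, 2])

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            PairedRanks(ranks_a=[1, 1, 3], ranks_b=[1, 2, 3])


class TestSurvivalFunctions:
    def test_empirical_hand_count(self):
        stats = MaxRankStats(max_rank=[1, 2, 3, 4], m_total=4)
        assert empirical_survival(stats, 0.5) == 0.75  # 2,3,4 qualify
        assert empirical_survival(stats, 1 / 4) == 1.0
        assert empirical_survival(stats, 1.01) == 0.0

    def test_empirical_nonincreasing_step(self):
        rng = np.random.default_rng(3)
        stats = random_max_ranks(25, rng)
        xs = np.linspace(0.01, 1.2, 60)
        vals = [empirical_survival(stats, x) for x in xs]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_ideal_branches(self):
        assert ideal_survival(0.35, 0.2) == 1.0
        assert ideal_survival(0.35, 1.0) == 0.0
        # midpoint of [pi1, 1]: 1 - (1/2)^2
        assert ideal_survival(0.35, 0.675) == pytest.approx(0.75)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_ideal_rejects_bad_pi1(self, bad):
        with pytest.raises(ValueError):
            ideal_survival(bad, 0.5)


class TestEstimatePi1:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = int(rng.integers(5, 50))
            stats = random_max_ranks(m, rng)
            est = estimate_pi1(stats, lam=0.9)
            brute = brute_mse_profile(stats, 0.9)
            np.testing.assert_allclose(est.mse_profile, brute, atol=1e-10)
            assert est.k_hat == int(np.argmin(brute)) + 1

    def test_profile_nonnegative_and_k_in_range(self):
        rng = np.random.default_rng(5)
        stats = random_max_ranks(30, rng)
        est = estimate_pi1(stats, lam=0.9)
        assert (est.mse_profile >= 0).all()
        assert 1 <= est.k_hat <= int(0.9 * 30)
        assert est.pi1_hat == est.k_hat / 30

    def test_ideal_split_recovery(self):
        # perfect split at pi1 = 0.35 with M=10,000: recovery within 0.01
        a, b, _ = simulate_ideal_ranks(0.35, 10_000, dataset_seed=0)
        stats = max_rank(PairedRanks(ranks_a=a, ranks_b=b))
        est = estimate_pi1(stats)
        assert abs(est.pi1_hat - 0.35) < 0.01

    def test_rejects_degenerate_inputs(self):
        stats = MaxRankStats(max_rank=[1, 2], m_total=2)
        with pytest.raises(ValueError):
            estimate_pi1(stats)
        stats5 = MaxRankStats(max_rank=[1, 2, 3, 4, 5], m_total=5)
        with pytest.raises(ValueError):
            estimate_pi1(stats5, lam=0.1)  # floor(0.5) = 0 candidates


class TestExpectedFalseDiscoveries:
    def test_direct_arithmetic(self):
        assert expected_false_discoveries(100, 150, 1000) == pytest.approx(
            2500 / 900
        )
        # l = M: algebraic cancellation to M - k
        assert expected_false_discoveries(40, 100, 100) == pytest.approx(60)
        assert expected_false_discoveries(10, 10, 100) == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            expected_false_discoveries(10, 9, 100)
        with pytest.raises(ValueError):
            expected_false_discoveries(10, 101, 100)


class TestMfdrCurve:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            m = int(rng.integers(6, 40))
            stats = random_max_ranks(m, rng)
            k_hat = int(rng.integers(1, m - 1))
            curve = mfdr_curve(stats, k_hat)
            l_grid, q, mfdr = brute_mfdr(stats, k_hat)
            assert np.array_equal(curve.l_grid, l_grid)
            assert np.array_equal(curve.q_of_l, q)
            np.testing.assert_allclose(curve.mfdr_of_l, mfdr)
            assert (curve.mfdr_of_l >= 0).all()

    def test_full_rejection_endpoint(self):
        # at l = M, Q(M) = M so mFDR = (M - k) / M exactly
        rng = np.random.default_rng(17)
        stats = random_max_ranks(30, rng)
        for k_hat in (1, 10, 29):
            curve = mfdr_curve(stats, k_hat)
            assert curve.mfdr_of_l[-1] == pytest.approx((30 - k_hat) / 30)

    def test_q_nondecreasing(self):
        stats = random_max_ranks(40, np.random.default_rng(19))
        curve = mfdr_curve(stats, 5)
        assert (np.diff(curve.q_of_l) >= 0).all()


class TestSelectThreshold:
    def _curve(self, mfdr_vals, k_hat):
        l_grid = np.arange(k_hat + 1, k_hat + 1 + len(mfdr_vals))
        return type(
            "C", (), {"l_grid": l_grid, "mfdr_of_l": np.asarray(mfdr_vals)}
        )()

    def test_all_below_alpha_gives_m(self):
        curve = self._curve([0.01, 0.02, 0.03], k_hat=4)
        assert select_threshold(curve, 0.05, 4) == 7

    def test_all_above_alpha_falls_back_to_k_hat(self):
        curve = self._curve([0.5, 0.6], k_hat=4)
        assert select_threshold(curve, 0.05, 4) == 4

    def test_non_monotone_curve_takes_largest_admissible(self):
        k = 3
        mfdr = [0.01, 0.9, 0.9, 0.9, 0.02, 0.9, 0.9]
        curve = self._curve(mfdr, k)
        n_hat = select_threshold(curve, 0.05, k)
        # exhaustive scan oracle
        admissible = [
            l for l, v in zip(curve.l_grid, mfdr) if v <= 0.05
        ]
        assert n_hat == max(admissible) == k + 5


class TestMarrPair:
    def test_identical_vectors_degenerate_case(self):
        # perfect correlation: Max_m equals the common rank, so calls are
        # exactly the top-N-hat ranked metabolites
        rng = np.random.default_rng(23)
        v = rng.normal(size=200)
        res = marr_pair(v, v, alpha=0.05, tie_seed=1)
        ranks = assign_ranks(v, tie_seed=0)
        assert np.array_equal(
            res.calls.astype(bool), ranks <= res.n_hat
        )

    def test_ideal_split_call_fraction(self):
        # pi1 = 0.35 perfect-split ranks: fraction called ~ 0.35 at alpha=0.01
        a, b, _ = simulate_ideal_ranks(0.35, 5000, dataset_seed=2)
        # feed ranks as values: rank 1 must be the largest value, so negate
        res = marr_pair(-a.astype(float), -b.astype(float), alpha=0.01, tie_seed=3)
        assert abs(res.n_reproducible / 5000 - 0.35) < 0.02

    def test_threshold_consistency(self):
        rng = np.random.default_rng(29)
        res = marr_pair(rng.normal(size=300), rng.normal(size=300), tie_seed=5)
        assert res.n_hat >= res.pi1.k_hat
        # calls agree with thresholding the max ranks
        assert np.array_equal(
            res.calls.astype(bool), res.max_ranks.max_rank <= res.n_hat
        )
        # the mFDR at the chosen threshold never exceeds alpha
        if res.n_hat > res.pi1.k_hat:
            at = np.flatnonzero(res.curve.l_grid == res.n_hat)[0]
            assert res.curve.mfdr_of_l[at] <= res.alpha

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            marr_pair([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(size=400), rng.normal(size=400)
        base = marr_pair(a, b, tie_seed=7)
        for f in (np.exp, lambda x: 3 * x + 10, lambda x: x**3):
            alt = marr_pair(f(a), f(b), tie_seed=7)
            assert np.array_equal(base.calls, alt.calls)
            assert base.n_hat == alt.n_hat
            assert base.pi1.k_hat == alt.pi1.k_hat
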