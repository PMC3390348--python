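import numpy as np
import pytest
import scipy.stats

from exprpatterns import (
    GeneList,
    ValidationError,
    directional_agreement,
    list_comparison_test,
    multiway_same_direction_test,
    overlap_permutation_p,
    overlap_test,
)


def signed(symbols, direction="up", name=""):
    return GeneList({s: direction for s in symbols}, name=name)


BG10 = {f"g{i}" for i in range(10)}


class TestOverlapTest:
    def test_hand_binomial_sum(self):
        # background 10, sizes 5 and 4, observed 4: P(Bin(10, 0.2) >= 4)
        a = signed([f"g{i}" for i in range(5)])
        b = signed([f"g{i}" for i in range(4)])
        res = overlap_test(a, b, BG10)
        assert res.observed == 4
        assert res.expected == pytest.approx(2.0)
        assert res.p == pytest.approx(0.1208738, rel=1e-5)

    def test_disjoint_lists_give_p_one(self):
        a = signed(["g0", "g1"])
        b = signed(["g5", "g6"])
        res = overlap_test(a, b, BG10)
        assert res.observed == 0
        assert res.p == pytest.approx(1.0)

    def test_member_outside_background_named(self):
        a = signed(["g0", "nope"])
        with pytest.raises(ValidationError, match="nope"):
            overlap_test(a, signed(["g1"]), BG10)

    def test_expected_is_product_over_background(self):
        rng = np.random.default_rng(51)
        bg = [f"g{i}" for i in range(40)]
        a = signed(rng.choice(bg, 12, replace=False))
        b = signed(rng.choice(bg, 9, replace=False))
        res = overlap_test(a, b, bg)
        assert res.expected == pytest.approx(12 * 9 / 40)

    def test_p_monotone_decreasing_in_observed(self):
        ps = []
        for obs in range(0, 5):
            a = signed([f"g{i}" for i in range(5)])
            b = signed([f"g{i}" for i in range(obs)]
                       + [f"g{9 - i}" for i in range(4 - obs)])
            ps.append(overlap_test(a, b, BG10).p)
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_concordance_partition(self):
        a = GeneList({"g0": "up", "g1": "down", "g2": "up", "g3": "up"})
        b = GeneList({"g0": "up", "g1": "up", "g2": "down", "g4": "up"})
        res = overlap_test(a, b, BG10)
        assert res.observed == 3
        assert (res.concordant_up, res.concordant_down, res.discordant) == (1, 0, 2)
        assert res.concordant_up + res.concordant_down + res.discordant == res.observed

    def test_agrees_with_monte_carlo_oracle(self):
        """Exact binomial tail vs simulation of the independent-marking
        overlap model on small backgrounds."""
        cases = [(50, 20, 15, 10), (30, 10, 10, 6), (10, 5, 4, 4)]
        for i, (N, a, b, obs) in enumerate(cases):
            exact = float(scipy.stats.binom.sf(obs - 1, N, (a / N) * (b / N)))
            mc = overlap_permutation_p(N, a, b, obs, draws=50_000, seed=100 + i)
            se = np.sqrt(exact * (1 - exact) / 50_000)
            assert abs(mc - exact) < 5 * max(se, 1e-4)

    def test_normal_approximation_close_for_moderate_p(self):
        a = signed([f"g{i}" for i in range(5)])
        b = signed([f"g{i}" for i in range(4)])
        exact = overlap_test(a, b, BG10).p
        approx = overlap_test(a, b, BG10, method="normal").p
        assert abs(exact - approx) < 0.05


class TestDirectionalAgreement:
    def test_identical_lists_fraction_one(self):
        a = GeneList({"g0": "up", "g1": "down"})
        assert directional_agreement(a, a) == (2, 2, 1.0)

    def test_opposite_signs_fraction_zero(self):
        a = GeneList({"g0": "up", "g1": "down"})
        b = GeneList({"g0": "down", "g1": "up"})
        n_agree, n_total, frac = directional_agreement(a, b)
        assert (n_agree, n_total, frac) == (0, 2, 0.0)

    def test_reference_counts_give_expected_fraction(self):
        # 81 up-concordant + 101 down-concordant of 189 overlapping genes
        a_entries, b_entries = {}, {}
        for i in range(81):
            a_entries[f"u{i}"] = b_entries[f"u{i}"] = "up"
        for i in range(101):
            a_entries[f"d{i}"] = b_entries[f"d{i}"] = "down"
        for i in range(7):
            a_entries[f"x{i}"] = "up"
            b_entries[f"x{i}"] = "down"
        n_agree, n_total, frac = directional_agreement(
            GeneList(a_entries), GeneList(b_entries)
        )
        assert (n_agree, n_total) == (182, 189)
        assert frac == pytest.approx(182 / 189)

    def test_unsigned_entry_rejected(self):
        a = GeneList({"g0": "up", "g1": "unsigned"})
        with pytest.raises(ValidationError, match="unsigned"):
            directional_agreement(a, a)


class TestMultiway:
    def test_two_identical_lists(self):
        bg = {f"g{i}" for i in range(100)}
        a = signed([f"g{i}" for i in range(20)])
        expected, observed, p = multiway_same_direction_test([a, a], bg)
        assert observed == 20
        assert expected == pytest.approx(100 * 0.2 * 0.2 * 0.5)
        assert p < 1e-10

    def test_three_study_expectation_formula(self):
        bg = {f"g{i}" for i in range(495)}
        lists = [
            signed([f"g{i}" for i in range(size)], direction="up")
            for size in (169, 148, 63)
        ]
        expected, _, _ = multiway_same_direction_test(lists, bg)
        assert expected == pytest.approx(
            495 * (169 / 495) * (148 / 495) * (63 / 495) / 4
        )
        assert expected == pytest.approx(1.606, abs=0.005)

    def test_disjoint_lists_give_p_one(self):
        bg = {f"g{i}" for i in range(30)}
        a = signed(["g0", "g1"])
        b = signed(["g5", "g6"])
        _, observed, p = multiway_same_direction_test([a, b], bg)
        assert observed == 0
        assert p == pytest.approx(1.0)

    def test_single_list_rejected(self):
        with pytest.raises(ValidationError):
            multiway_same_direction_test([signed(["g0"])], BG10)


class TestListComparison:
    def test_exact_binomial_oracle(self):
        p = list_comparison_test(15, 7, 0.175)
        k = np.arange(7, 16)
        oracle = scipy.stats.binom.pmf(k, 15, 0.175).sum()
        assert p == pytest.approx(oracle, rel=1e-10)

    def test_zero_hits_give_one(self):
        assert list_comparison_test(15, 0, 0.175) == pytest.approx(1.0)

    def test_reference_comparisons_significant(self):
        # published-list comparisons at the 17.5% chance baseline
        for n_sel, n_hit in [(15, 7), (28, 12)]:
            assert list_comparison_test(n_sel, n_hit, 0.175) < 0.05

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValidationError):
            list_comparison_test(10, 5, 0.0)
        with pytest.raises(ValidationError):
            list_comparison_test(10, 11, 0.5)
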