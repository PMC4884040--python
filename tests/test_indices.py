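import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_random_dist
from hequity import (
    Distribution,
    DomainError,
    Unit,
    ValidationError,
    atkinson,
    classify_gini,
    concentration_curve,
    concentration_index,
    curve_areas,
    dissimilarity_index,
    ede_fraction,
    fractional_ranks,
    gini,
    interpret_ci,
    theil,
    theil_decompose,
    theil_offenders,
)


class TestGini:
    def test_perfect_equality_is_zero(self, equal_dist):
        assert gini(equal_dist) == 0.0

    def test_two_unit_hand_value(self, two_unit_dist):
        assert gini(two_unit_dist) == pytest.approx(0.3, abs=1e-12)

    def test_one_of_n_holds_all(self):
        d = Distribution(
            [Unit(f"u{i}", 10, 100.0 if i == 0 else 0.0) for i in range(5)]
        )
        assert gini(d) == pytest.approx(0.8, abs=1e-12)  # 1 - 1/n

    def test_equals_twice_lorenz_area(self, rng):
        from hequity import lorenz_curve

        for _ in range(200):
            d = make_random_dist(rng)
            assert gini(d) == pytest.approx(
                2 * curve_areas(lorenz_curve(d)).area_A, abs=1e-12
            )

    def test_transfer_principle(self, rng):
        """A small transfer from a higher-per-capita unit to a lower one
        (without rank crossing) never increases Gini."""
        for _ in range(50):
            d = make_random_dist(rng, n=6)
            pc = d.per_capita
            hi, lo = int(np.argmax(pc)), int(np.argmin(pc))
            gap = (pc[hi] - pc[lo]) * min(d.populations[hi], d.populations[lo])
            eps = 0.01 * gap
            res = d.resources.copy()
            res[hi] -= eps
            res[lo] += eps
            assert gini(d.replace_resources(res)) <= gini(d) + 1e-12

    def test_scale_and_replication_invariance(self, rng):
        d = make_random_dist(rng, n=5)
        assert gini(d.replace_resources(d.resources * 137.5)) == pytest.approx(
            gini(d), abs=1e-12
        )
        dup = Distribution(
            [
                Unit(f"{u.id}{t}", u.population / 2, u.resource / 2)
                for u in d.units
                for t in ("a", "b")
            ]
        )
        assert gini(dup) == pytest.approx(gini(d), abs=1e-12)

    def test_small_sample_correction(self, two_unit_dist):
        assert gini(two_unit_dist, small_sample_correction=True) == pytest.approx(
            0.6, abs=1e-12
        )


class TestClassifyGini:
    @pytest.mark.parametrize(
        "g,label",
        [
            (0.0, "perfect_equity"),
            (0.25, "perfect_equity"),
            (0.2999999, "perfect_equity"),
            (0.3, "normal"),
            (0.35, "normal"),
            (0.4, "normal"),
            (0.4000001, "alert"),
            (0.45, "alert"),
            (0.6, "alert"),
            (0.6000001, "highly_inequitable"),
            (0.65, "highly_inequitable"),
            (1.0, "highly_inequitable"),
        ],
    )
    def test_band_boundaries(self, g, label):
        assert classify_gini(g) == label

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            classify_gini(-0.1)
        with pytest.raises(DomainError):
            classify_gini(1.1)


class TestFractionalRanks:
    def test_equal_population_midpoints(self):
        d = Distribution([Unit(f"u{i}", 25, 10, ses=float(i)) for i in range(4)])
        r = fractional_ranks(d)
        assert np.allclose(r.ranks, [0.125, 0.375, 0.625, 0.875])

    def test_weighted_mean_rank_is_half(self, rng):
        for _ in range(30):
            d = make_random_dist(rng, with_ses=True)
            r = fractional_ranks(d)
            assert float(r.weights @ r.ranks) == pytest.approx(0.5, abs=1e-12)

    def test_ses_ties_share_block_midpoint(self):
        d = Distribution(
            [
                Unit("a", 10, 1, ses=1.0),
                Unit("b", 30, 1, ses=1.0),
                Unit("c", 60, 1, ses=2.0),
            ]
        )
        r = fractional_ranks(d)
        assert np.allclose(r.ranks, [0.2, 0.2, 0.7])
        assert float(r.weights @ r.ranks) == pytest.approx(0.5, abs=1e-12)


class TestConcentrationIndex:
    def test_constant_per_capita_is_zero(self):
        d = Distribution([Unit(f"u{i}", 10, 5, ses=float(i)) for i in range(6)])
        assert concentration_index(d) == pytest.approx(0.0, abs=1e-12)

    def test_four_unit_hand_value(self):
        # poorest->richest per-capita (1,1,1,5), equal populations
        d = Distribution(
            [Unit(f"u{i}", 10, h * 10, ses=float(i)) for i, h in enumerate([1, 1, 1, 5])]
        )
        assert concentration_index(d) == pytest.approx(0.375, abs=1e-12)

    def test_reversing_ses_negates(self, rng):
        for _ in range(20):
            d = make_random_dist(rng, with_ses=True)
            rev = Distribution(
                [
                    Unit(u.id, u.population, u.resource, ses=-u.ses)
                    for u in d.units
                ]
            )
            assert concentration_index(rev) == pytest.approx(
                -concentration_index(d), abs=1e-10
            )

    @pytest.mark.parametrize("n", [10, 100, 1000])
    def test_agrees_with_signed_curve_area(self, n):
        """Covariance form vs 2 x signed area between concentration curve
        and diagonal, converging as n grows (equal-weight units)."""
        rng = np.random.default_rng(n)
        ses = np.arange(n, dtype=float)
        res = rng.lognormal(0, 0.7, size=n) * 10
        d = Distribution(
            [Unit(f"u{i}", 1.0, float(res[i]), ses=float(ses[i])) for i in range(n)]
        )
        # signed: area_A > 0 when the curve is below the diagonal (pro-rich)
        area_ci = 2 * curve_areas(concentration_curve(d)).area_A
        assert concentration_index(d) == pytest.approx(area_ci, abs=5.0 / n)

    def test_missing_ses_raises(self, two_unit_dist):
        with pytest.raises(ValidationError):
            concentration_index(two_unit_dist)


class TestInterpretCi:
    @pytest.mark.parametrize(
        "ci,label",
        [
            (-0.1, "concentrated_on_poor"),
            (0.0, "proportionate"),
            (1e-15, "proportionate"),
            (0.1, "concentrated_on_rich"),
        ],
    )
    def test_labels(self, ci, label):
        assert interpret_ci(ci) == label

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            interpret_ci(1.5)


class TestTheil:
    def test_proportional_allocation_is_zero(self, rng):
        pops = rng.uniform(10, 500, size=5)
        d = Distribution(
            [Unit(f"u{i}", float(p), float(p) * 3.7) for i, p in enumerate(pops)]
        )
        assert theil(d) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # P=(0.5,0.5), Y=(0.25,0.75): 0.5 ln2 + 0.5 ln(2/3)
        d = Distribution([Unit("a", 50, 25), Unit("b", 50, 75)])
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        assert theil(d) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1438, abs=5e-5)

    def test_zero_resource_unit_diverges_with_offenders(self):
        d = Distribution([Unit("a", 50, 50), Unit("b", 50, 0)])
        assert theil(d) == math.inf
        assert theil_offenders(d) == ["b"]

    def test_scale_and_replication_invariance(self, rng):
        d = make_random_dist(rng, n=5)
        assert theil(d.replace_resources(d.resources * 42.0)) == pytest.approx(
            theil(d), abs=1e-12
        )
        dup = Distribution(
            [
                Unit(f"{u.id}{t}", u.population / 2, u.resource / 2)
                for u in d.units
                for t in ("a", "b")
            ]
        )
        assert theil(dup) == pytest.approx(theil(d), abs=1e-12)


class TestTheilDecomposition:
    def test_single_group_all_within(self, rng):
        d = make_random_dist(rng, with_groups=True, n_groups=1)
        dec = theil_decompose(d)
        assert dec.between == pytest.approx(0.0, abs=1e-12)
        assert dec.within == pytest.approx(dec.total, abs=1e-12)

    def test_each_unit_own_group_all_between(self, rng):
        d0 = make_random_dist(rng, n=6)
        d = Distribution(
            [
                Unit(u.id, u.population, u.resource, group=u.id)
                for u in d0.units
            ]
        )
        dec = theil_decompose(d)
        assert dec.within == pytest.approx(0.0, abs=1e-12)
        assert dec.between == pytest.approx(dec.total, abs=1e-12)

    def test_two_group_hand_value(self):
        # 2 groups of 2 equal-pop units; group resource shares (0.3, 0.7),
        # equal split inside each group -> within = 0
        d = Distribution(
            [
                Unit("a1", 25, 15, group="A"),
                Unit("a2", 25, 15, group="A"),
                Unit("b1", 25, 35, group="B"),
                Unit("b2", 25, 35, group="B"),
            ]
        )
        dec = theil_decompose(d)
        expected_between = 0.5 * math.log(0.5 / 0.3) + 0.5 * math.log(0.5 / 0.7)
        assert dec.within == pytest.approx(0.0, abs=1e-12)
        assert dec.between == pytest.approx(expected_between, abs=1e-12)
        assert expected_between == pytest.approx(0.0872, abs=5e-5)

    def test_additive_identity_and_rates(self, rng):
        for _ in range(100):
            d = make_random_dist(rng, with_groups=True)
            dec = theil_decompose(d)
            assert dec.within + dec.between == pytest.approx(dec.total, abs=1e-10)
            if dec.contribution_rates is not None:
                assert sum(dec.contribution_rates.values()) == pytest.approx(
                    1.0, abs=1e-12
                )

    def test_unlabeled_unit_raises(self, two_unit_dist):
        with pytest.raises(ValidationError):
            theil_decompose(two_unit_dist)


class TestAtkinson:
    def test_equal_allocation_zero_for_any_epsilon(self, equal_dist):
        for eps in (0.5, 1.0, 2.0, 5.0):
            assert atkinson(equal_dist, eps) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_eps2(self):
        # f=(0.5,0.5), y/mean=(0.5,1.5): 1 - [0.5*2 + 0.5*(2/3)]^-1 = 0.25
        d = Distribution([Unit("a", 50, 25), Unit("b", 50, 75)])
        assert atkinson(d, 2.0) == pytest.approx(0.25, abs=1e-12)

    def test_hand_value_eps1(self):
        d = Distribution([Unit("a", 50, 25), Unit("b", 50, 75)])
        assert atkinson(d, 1.0) == pytest.approx(1 - math.sqrt(0.75), abs=1e-12)

    def test_branches_agree_near_eps_one(self, rng):
        for _ in range(100):
            d = make_random_dist(rng)
            a1 = atkinson(d, 1.0)
            assert atkinson(d, 1.0 + 1e-6) == pytest.approx(a1, abs=1e-6)
            assert atkinson(d, 1.0 - 1e-6) == pytest.approx(a1, abs=1e-6)

    def test_nondecreasing_in_epsilon(self, rng):
        for _ in range(20):
            d = make_random_dist(rng)
            vals = [atkinson(d, e) for e in (0.25, 0.5, 1.0, 2.0, 4.0)]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_vanishes_as_epsilon_to_zero(self, rng):
        d = make_random_dist(rng)
        assert atkinson(d, 1e-8) == pytest.approx(0.0, abs=1e-6)

    def test_zero_resource_unit_with_high_epsilon_is_one(self):
        d = Distribution([Unit("a", 50, 50), Unit("b", 50, 0)])
        assert atkinson(d, 1.0) == 1.0
        assert atkinson(d, 2.0) == 1.0
        assert 0 < atkinson(d, 0.5) < 1  # finite below eps=1

    def test_epsilon_domain(self, equal_dist):
        with pytest.raises(DomainError):
            atkinson(equal_dist, 0.0)
        with pytest.raises(DomainError):
            atkinson(equal_dist, -1.0)


class TestEdeFraction:
    @pytest.mark.parametrize("a,frac", [(0.20, 0.80), (0.0, 1.0), (0.5, 0.5)])
    def test_values(self, a, frac):
        assert ede_fraction(a) == pytest.approx(frac, abs=1e-15)

    def test_domain(self):
        with pytest.raises(DomainError):
            ede_fraction(1.0)
        with pytest.raises(DomainError):
            ede_fraction(-0.1)


class TestDissimilarityIndex:
    def test_proportional_groups_zero(self):
        d = Distribution(
            [
                Unit(f"u{i}", p, p * 2.0, group=g)
                for i, (p, g) in enumerate(
                    [(10, "a"), (20, "a"), (30, "b"), (40, "c"), (50, "d")]
                )
            ]
        )
        assert dissimilarity_index(d) == pytest.approx(0.0, abs=1e-12)

    def test_two_group_hand_value(self):
        # S_h = (0.7, 0.3), S_p = (0.5, 0.5) -> ID = 0.2
        d = Distribution(
            [Unit("a", 50, 70, group="A"), Unit("b", 50, 30, group="B")]
        )
        assert dissimilarity_index(d) == pytest.approx(0.2, abs=1e-12)

    @given(sh=st.floats(0.01, 0.99), sp=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_two_group_complement_symmetry(self, sh, sp):
        """With 2 groups ID = |S_1h - S_1p| because shares sum to 1."""
        d = Distribution(
            [
                Unit("a", sp * 100, sh * 100, group="A"),
                Unit("b", (1 - sp) * 100, (1 - sh) * 100, group="B"),
            ]
        )
        assert dissimilarity_index(d) == pytest.approx(abs(sh - sp), abs=1e-12)

    def test_bounded_by_one(self, rng):
        for _ in range(50):
            d = make_random_dist(rng, with_groups=True)
            assert 0.0 <= dissimilarity_index(d) <= 1.0
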