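"""Tests of the Euler-Lotka solver, gradients and landscape structure."""

import math
import random

import numpy as np
import pytest
from scipy.optimize import brentq

from bdage.fitness import (
    fitness_gradient,
    landscape,
    malthusian,
    renewal_residual,
    viability_threshold,
)
from bdage.model import Intensities, Trait


class TestRenewalResidual:
    def test_zero_lambda_is_net_reproduction_minus_one(self, unit_intensities):
        # menopause trait: R0 = i_b * x_b
        assert renewal_residual(0.0, Trait(1.2, 1.6), unit_intensities) == pytest.approx(0.2)
        # mixed trait: R0 = x_d + (1 - exp(-(x_b - x_d)))
        expected = 1.0 + (1.0 - math.exp(-1.0)) - 1.0
        assert renewal_residual(0.0, Trait(2.0, 1.0), unit_intensities) == pytest.approx(
            expected
        )

    def test_printed_isocline_is_a_root(self, unit_intensities):
        """The 0.7 isocline passes through the trait (2.45, 1.05)."""
        assert abs(renewal_residual(0.7, Trait(2.45, 1.05), unit_intensities)) < 5e-3

    def test_sterile_trait_returns_minus_one(self, unit_intensities):
        assert renewal_residual(0.3, Trait(-1.0, 1.0), unit_intensities) == -1.0
        assert renewal_residual(-2.0, Trait(0.0, 1.0), unit_intensities) == -1.0

    def test_matches_numerical_quadrature(self, unit_intensities):
        from scipy.integrate import quad

        rng = random.Random(7)
        for _ in range(20):
            xb = rng.uniform(0.2, 6.0)
            xd = rng.uniform(-2.0, 6.0)
            lam = rng.uniform(-0.5, 1.0)

            def integrand(a):
                m = max(xd, 0.0)
                s = 1.0 if a < m else math.exp(-1.0 * (a - m))
                return s * math.exp(-lam * a)

            expected = quad(integrand, 0, xb, points=[min(max(xd, 0.0), xb)])[0] - 1.0
            got = renewal_residual(lam, Trait(xb, xd), unit_intensities)
            assert got == pytest.approx(expected, abs=1e-9)


class TestMalthusian:
    def test_isocline_anchor_non_lansing(self, unit_intensities):
        res = malthusian(Trait(2.45, 1.05), unit_intensities, "non_lansing")
        assert res.lambda_ == pytest.approx(0.70, abs=0.01)
        assert abs(res.residual) < 1e-10
        assert res.branch == "normal"

    def test_isocline_anchor_lansing(self, unit_intensities):
        res = malthusian(Trait(2.45, 1.05), unit_intensities, "lansing")
        assert res.lambda_ == pytest.approx(0.10, abs=0.01)
        assert res.branch == "normal"  # normal->normal branch dominates here

    def test_menopause_root_against_bisection(self, unit_intensities):
        """For x_d >= x_b the root solves lambda = i_b (1 - exp(-lambda x_b))."""
        oracle = brentq(
            lambda u: (1 - math.exp(-1.2 * u)) / u - 1.0, 1e-9, 1.0, xtol=1e-12
        )
        res = malthusian(Trait(1.2, 1.6), unit_intensities)
        assert res.lambda_ == pytest.approx(oracle, abs=1e-8)
        assert res.lambda_ == pytest.approx(0.313, abs=1e-3)

    def test_reference_founder_pair_is_fitness_matched(self, unit_intensities):
        lam_l = malthusian(Trait(1.5, 1.3), unit_intensities, "lansing").lambda_
        lam_n = malthusian(Trait(1.5, 0.83), unit_intensities, "non_lansing").lambda_
        assert lam_l == pytest.approx(0.4227, abs=1e-3)
        assert lam_n == pytest.approx(0.4295, abs=1e-3)
        assert abs(lam_l - lam_n) < 0.01

    def test_newton_agrees_with_bisection_oracle(self, unit_intensities):
        rng = random.Random(21)
        for _ in range(50):
            trait = Trait(rng.uniform(0.3, 8.0), rng.uniform(-3.0, 8.0))
            got = malthusian(trait, unit_intensities).lambda_

            def f(lam):
                return renewal_residual(lam, trait, unit_intensities)

            oracle = brentq(f, -50.0, 1.0, xtol=1e-12)
            assert got == pytest.approx(oracle, abs=1e-8)

    def test_sign_matches_net_reproduction(self, unit_intensities):
        rng = random.Random(5)
        for _ in range(50):
            trait = Trait(rng.uniform(0.2, 4.0), rng.uniform(-2.0, 4.0))
            r0 = renewal_residual(0.0, trait, unit_intensities) + 1.0
            lam = malthusian(trait, unit_intensities).lambda_
            assert math.copysign(1, lam) == math.copysign(1, r0 - 1.0) or r0 == 1.0

    def test_lambda_capped_by_birth_intensity(self):
        for ib, idv in ((1.0, 1.0), (0.5, 2.0), (2.0, 0.3)):
            ints = Intensities(ib, idv)
            for trait in (Trait(50.0, 50.0), Trait(3.0, 1.0), Trait(100.0, 90.0)):
                assert malthusian(trait, ints).lambda_ <= ib
                assert malthusian(trait, ints, "lansing").lambda_ <= ib
        # joint large-trait limit approaches the cap
        big = malthusian(Trait(500.0, 499.0), Intensities(1, 1)).lambda_
        assert big == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_both_genes(self, unit_intensities):
        for lineage in ("non_lansing", "lansing"):
            lams_b = [
                malthusian(Trait(xb, 1.0), unit_intensities, lineage).lambda_
                for xb in (1.2, 1.8, 2.6, 4.0)
            ]
            assert lams_b == sorted(lams_b)
            lams_d = [
                malthusian(Trait(3.0, xd), unit_intensities, lineage).lambda_
                for xd in (0.0, 0.8, 1.6, 2.4, 3.2)
            ]
            assert lams_d == sorted(lams_d)

    def test_lansing_below_non_lansing_iff_below_diagonal(self, unit_intensities):
        rng = random.Random(11)
        for _ in range(40):
            trait = Trait(rng.uniform(0.5, 6.0), rng.uniform(-1.0, 7.0))
            lam_n = malthusian(trait, unit_intensities, "non_lansing").lambda_
            lam_l = malthusian(trait, unit_intensities, "lansing").lambda_
            if trait.x_d >= trait.x_b or trait.x_d <= 0:
                # above the diagonal the rule never fires; at x_d <= 0 the
                # clamped hazard makes the pinned offspring dynamically
                # identical to the parent, so the lineages coincide too
                assert lam_l == pytest.approx(lam_n, abs=1e-10)
            else:
                assert lam_l < lam_n

    def test_sterile_trait_lambda_minus_infinity(self, unit_intensities):
        assert malthusian(Trait(-2.0, 1.0), unit_intensities).lambda_ == -math.inf


class TestGradient:
    def test_matches_finite_differences(self, unit_intensities):
        for trait, lineage in [
            (Trait(2.45, 1.05), "non_lansing"),
            (Trait(2.45, 1.05), "lansing"),
            (Trait(1.2, 1.6), "non_lansing"),
            (Trait(3.0, 0.5), "lansing"),
        ]:
            gb, gd = fitness_gradient(trait, unit_intensities, lineage)
            h = 1e-6

            def lam(t):
                return malthusian(t, unit_intensities, lineage).lambda_

            fd_b = (lam(Trait(trait.x_b + h, trait.x_d)) - lam(Trait(trait.x_b - h, trait.x_d))) / (2 * h)
            fd_d = (lam(Trait(trait.x_b, trait.x_d + h)) - lam(Trait(trait.x_b, trait.x_d - h))) / (2 * h)
            assert gb == pytest.approx(fd_b, rel=1e-4, abs=1e-9)
            assert gd == pytest.approx(fd_d, rel=1e-4, abs=1e-9)

    def test_components_nonnegative(self, unit_intensities):
        rng = random.Random(3)
        for _ in range(30):
            trait = Trait(rng.uniform(0.5, 6.0), rng.uniform(-1.0, 7.0))
            for lineage in ("non_lansing", "lansing"):
                gb, gd = fitness_gradient(trait, unit_intensities, lineage)
                assert gb >= 0 and gd >= 0

    def test_selection_shadow_along_diagonal(self, unit_intensities):
        """The gradient norm shrinks as the trait grows along x_b = x_d."""
        norms = [
            math.hypot(*fitness_gradient(Trait(x, x), unit_intensities))
            for x in (1.0, 2.0, 4.0)
        ]
        assert norms[0] > norms[1] > norms[2]

    def test_lansing_gradient_stronger_below_diagonal(self, unit_intensities):
        """At (2.45, 1.05) the Lansing lineage sits on a much steeper slope."""
        g_n = math.hypot(*fitness_gradient(Trait(2.45, 1.05), unit_intensities, "non_lansing"))
        g_l = math.hypot(*fitness_gradient(Trait(2.45, 1.05), unit_intensities, "lansing"))
        assert g_l / g_n > 2.0

    def test_sterile_trait_rejected(self, unit_intensities):
        with pytest.raises(ValueError):
            fitness_gradient(Trait(-1.0, 0.5), unit_intensities)


class TestLandscape:
    def test_structure(self, unit_intensities):
        grid = landscape(
            np.linspace(0.5, 4.0, 8), np.linspace(0.0, 4.0, 9), unit_intensities
        )
        assert grid.lambda_lansing.shape == (9, 8)
        # Lansing never exceeds non-Lansing; equality exactly above the diagonal
        assert (grid.lambda_lansing <= grid.lambda_non_lansing + 1e-12).all()
        for i, xd in enumerate(grid.x_d_axis):
            for j, xb in enumerate(grid.x_b_axis):
                if xd >= xb:
                    assert grid.lambda_lansing[i, j] == grid.lambda_non_lansing[i, j]

    def test_reference_grid_point(self, unit_intensities):
        grid = landscape([2.45], [1.05], unit_intensities)
        assert grid.lambda_non_lansing[0, 0] == pytest.approx(0.70, abs=0.01)
        assert grid.lambda_lansing[0, 0] == pytest.approx(0.10, abs=0.01)

    def test_subviable_region_has_nonpositive_lambda(self, unit_intensities):
        grid = landscape(
            np.linspace(0.1, 1.0, 6), np.linspace(0.0, 3.0, 5), unit_intensities
        )
        # at i_b * x_b = 1 exactly, lambda = 0 up to solver tolerance
        assert (grid.lambda_non_lansing <= 1e-9).all()


def test_viability_threshold():
    assert viability_threshold(Intensities(0.01, 1.0)) == pytest.approx(100.0)
    assert viability_threshold(Intensities(1.0, 1.0)) == pytest.approx(1.0)
    assert viability_threshold(Intensities(2.0, 1.0)) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        viability_threshold(Intensities(0.0, 1.0))
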