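"""Ligand-field hyperfine decomposition against the published anchors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histbrace.ligand_field import (ThermoCoupling,
                                    decompose_hyperfine, dz2_mixing,
                                    fermi_contact, kappa_from_aiso,
                                    recompose_parallel, solve_spin_density,
                                    stability_ratio)
from histbrace.spin_core import GTensor

G_FREE = GTensor(2.027, 2.095, 2.261)
G_BOUND = GTensor(2.042, 2.053, 2.205)
AISO_FREE = 9.67
AISO_BOUND = -208.33


class TestFermiContact:
    def test_substrate_free(self):
        assert fermi_contact(AISO_FREE, G_FREE) == pytest.approx(-139, abs=2)

    def test_substrate_bound(self):
        assert fermi_contact(AISO_BOUND, G_BOUND) == pytest.approx(-324, abs=2)

    def test_zero_kappa_case(self):
        aiso = (1180.0 / 3.0) * sum(G_FREE.dg)
        assert fermi_contact(aiso, G_FREE) == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_aiso(self):
        f0 = fermi_contact(0.0, G_FREE)
        assert fermi_contact(10.0, G_FREE) - f0 == pytest.approx(10.0)
        assert fermi_contact(-50.0, G_FREE) - f0 == pytest.approx(-50.0)

    def test_rejects_non_positive_pd(self):
        with pytest.raises(ValueError):
            fermi_contact(10.0, G_FREE, Pd=-1.0)


class TestSpinDensity:
    def test_substrate_free_x_band(self):
        kappa = kappa_from_aiso(AISO_FREE, G_FREE)
        assert solve_spin_density(-336, G_FREE, kappa, 0.02) == pytest.approx(
            0.82, abs=0.02)

    def test_substrate_free_q_band(self):
        kappa = kappa_from_aiso(AISO_FREE, G_FREE)
        assert solve_spin_density(-340, G_FREE, kappa, 0.02) == pytest.approx(
            0.82, abs=0.02)

    def test_isotropic_limit_zero_density(self):
        g_iso = GTensor(2.0023, 2.0023, 2.0023)
        # with dg = 0 and kappa = -A3/Pd the dipolar term must vanish
        assert solve_spin_density(-100.0, g_iso, 100.0 / 1180.0, 0.0) == \
            pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_grid_search(self):
        """Brute-force scan of the A3 equation matches the root finder."""
        kappa = kappa_from_aiso(AISO_FREE, G_FREE)
        grid = np.arange(0.0, 1.2, 1e-5)
        a3s = -1180.0 * (kappa + 4.0 * grid * (0.98 - 0.02) / 7.0
                         - a3_helper(G_FREE, 0.02))
        best = grid[np.argmin(np.abs(a3s - (-336.0)))]
        solved = solve_spin_density(-336.0, G_FREE, kappa, 0.02)
        assert solved == pytest.approx(best, abs=1e-5)

    def test_inconsistent_inputs_raise(self):
        with pytest.raises(ValueError):
            solve_spin_density(-5000.0, G_FREE, 0.1, 0.02)


def a3_helper(g, b2):
    """The alpha^2-independent part of the A3 bracket (for the grid scan)."""
    a, b = math.sqrt(1 - b2), math.sqrt(b2)
    dg1, dg2, dg3 = g.dg
    return ((3 * a - 3 * b) * dg2 / (14 * (a + 3 * b))
            + (3 * a + 3 * b) * dg1 / (14 * (a - 3 * b)) + dg3)


class TestDecomposition:
    def test_substrate_free_published_row(self):
        """Signs and parallel magnitudes of the five-coordinate breakdown."""
        d = decompose_hyperfine(G_FREE, AISO_FREE, -336.0, b2=0.02)
        assert d.fermi == pytest.approx(-139, abs=5)
        assert d.dipolar_para == pytest.approx(-533, abs=5)
        assert d.orbital_para == pytest.approx(332, abs=5)
        assert d.alpha2 == pytest.approx(0.82, abs=0.02)
        # perpendicular terms: sign and 20% only (leading order)
        assert d.dipolar_perp == pytest.approx(281, rel=0.2)
        assert d.orbital_perp == pytest.approx(70, rel=0.2)
        assert d.perp_approximate

    @pytest.mark.parametrize("aiso,row", [
        (AISO_BOUND, dict(fermi=-324, dip=-558, orb=262, alpha2=0.83)),
        (-261.67, dict(fermi=-380, dip=-504, orb=264, alpha2=0.75)),
    ])
    def test_substrate_bound_published_rows(self, aiso, row):
        """Four-coordinate rows, with the post-substrate d(z²) mixing of 0.5%."""
        d = decompose_hyperfine(G_BOUND, aiso, -620.0, b2=0.005)
        assert d.fermi == pytest.approx(row["fermi"], abs=5)
        assert d.dipolar_para == pytest.approx(row["dip"], abs=5)
        assert d.orbital_para == pytest.approx(row["orb"], abs=5)
        assert d.alpha2 == pytest.approx(row["alpha2"], abs=0.02)

    def test_all_published_signs_reproduced(self):
        for g, aiso, a3, b2 in [(G_FREE, AISO_FREE, -336.0, 0.02),
                                (G_BOUND, AISO_BOUND, -620.0, 0.005)]:
            d = decompose_hyperfine(g, aiso, a3, b2=b2)
            assert d.fermi < 0 and d.dipolar_para < 0
            assert d.dipolar_perp > 0 and d.orbital_para > 0
            assert d.orbital_perp > 0

    def test_isotropic_degenerate_case(self):
        g_iso = GTensor(2.0023, 2.0023, 2.0023)
        d = decompose_hyperfine(g_iso, -50.0, -50.0, b2=0.0)
        assert d.fermi == pytest.approx(-50.0)
        assert d.dipolar_para == pytest.approx(0.0, abs=1e-9)
        assert d.orbital_para == pytest.approx(0.0, abs=1e-9)
        assert d.alpha2 == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("g,aiso,a3,b2", [
        (G_FREE, AISO_FREE, -336.0, 0.02),
        (G_FREE, AISO_FREE, -340.0, 0.02),
        (G_BOUND, AISO_BOUND, -620.0, 0.005),
        (G_BOUND, -261.67, -620.0, 0.02),
    ])
    def test_recompose_is_identity_on_a3(self, g, aiso, a3, b2):
        d = decompose_hyperfine(g, aiso, a3, b2=b2)
        assert recompose_parallel(d) == pytest.approx(a3, abs=1e-9)

    def test_recompose_published_rows(self):
        from histbrace.ligand_field import HyperfineDecomposition
        q_row = HyperfineDecomposition(-139, -533, 281, 332, 70, 0.82)
        assert recompose_parallel(q_row) == -340  # Q-band |A3|
        x_row = HyperfineDecomposition(-324, -558, 279, 262, 53, 0.83)
        assert recompose_parallel(x_row) == -620  # chitin X-band |A3|


class TestDz2Mixing:
    def test_fixed_default(self):
        assert dz2_mixing(G_FREE) == 0.02

    def test_axial_limit_zero(self):
        assert dz2_mixing(GTensor(2.03, 2.03, 2.2), mode="estimate") == 0.0

    def test_estimate_monotone_in_splitting(self):
        prev = -1.0
        for g2 in (2.03, 2.05, 2.07, 2.09):
            est = dz2_mixing(GTensor(2.03, g2, 2.3), mode="estimate")
            assert est >= prev
            prev = est

    def test_estimate_calibrated_on_free_anchor(self):
        assert dz2_mixing(G_FREE, mode="estimate") == pytest.approx(0.02,
                                                                    abs=1e-3)


class TestStabilityRatio:
    def test_published_substrate_coupling(self):
        r = stability_ratio(ThermoCoupling(dE1=8.2, dE2=0.0))
        assert r == pytest.approx(1.04e6, rel=0.01)
        assert r >= 1e6

    def test_zero_difference_is_unity(self):
        assert stability_ratio(ThermoCoupling(0.0, 0.0)) == 1.0

    def test_rt_ln10_gives_factor_ten(self):
        ddE = 1.98720e-3 * 298.0 * math.log(10.0)
        assert stability_ratio(ThermoCoupling(ddE, 0.0)) == pytest.approx(
            10.0, rel=1e-4)

    @given(st.floats(-20, 20))
    @settings(max_examples=50, derandomize=True)
    def test_reciprocal_symmetry(self, x):
        prod = stability_ratio(ThermoCoupling(x, 0.0)) * \
            stability_ratio(ThermoCoupling(-x, 0.0))
        assert prod == pytest.approx(1.0, rel=1e-9)
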