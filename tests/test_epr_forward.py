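"""CW powder simulation: engine agreement, powder invariants, fitting."""

import dataclasses
import warnings

import numpy as np
import pytest

from histbrace.constants import MHZ_PER_MT
from histbrace.epr_forward import (eigenfields_exact, fit_spectrum,
                                   orientation_grid, read_spectrum,
                                   resonance_fields_perturbative,
                                   simulate_powder, write_spectrum)
from histbrace.spin_core import (CuHyperfine, GTensor, SpinSystem,
                                 resonance_field)

ISO_SYSTEM = SpinSystem(GTensor(2.0023, 2.0023, 2.0023),
                        CuHyperfine(0, 0, 0, ("+", "+", "+")),
                        mw_frequency=9.3046)


def area(spec):
    return np.trapezoid(spec.absorption, spec.field_mt)


class TestEngines:
    def test_hyperfine_free_isotropic_closed_form(self):
        for engine in (eigenfields_exact,
                       lambda s, v: resonance_fields_perturbative(
                           s, v, include_nitrogens=False)):
            lines = engine(ISO_SYSTEM, [0, 0, 1])
            fields = {round(b, 3) for b, _ in lines}
            assert fields == {round(resonance_field(2.0023, 9.3046), 3)}

    def test_first_order_comb_spacing_along_g3(self, bound_x):
        """|A3| = 620 MHz along axis 3: four lines ~20.1 mT apart."""
        lines = eigenfields_exact(bound_x, [0, 0, 1])
        strong = sorted(b for b, a in lines if a > 0.05)
        assert len(strong) == 4
        spacing = np.diff(strong).mean()
        expected = 620.0 / (2.205 * MHZ_PER_MT)
        assert spacing == pytest.approx(expected, rel=0.02)

    def test_second_order_shift_symmetric_about_comb(self, free_x):
        """The mI-dependent second-order shifts displace the outer lines
        asymmetrically relative to the naive first-order comb."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lines = resonance_fields_perturbative(free_x, [0, 0, 1],
                                                  include_nitrogens=False)
        strong = sorted(b for b, a in lines if a > 0.05)
        gaps = np.diff(strong)
        # first order alone would give equal gaps; second order breaks that
        assert not np.allclose(gaps, gaps.mean(), atol=1e-3)

    def test_engines_agree_on_reference_systems(self, reference_systems):
        """Perturbative vs exact fields within 0.1 mT, random orientations."""
        rng = np.random.default_rng(42)
        for label in ("free_X_14N", "chitin_X_14N"):
            sys_ = reference_systems[label]
            for _ in range(6):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                exact = [b for b, a in eigenfields_exact(sys_, v) if a > 0.05]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pert = [b for b, a in resonance_fields_perturbative(
                        sys_, v, include_nitrogens=False) if a > 0.05]
                for b in pert:
                    assert min(abs(np.array(exact) - b)) < 0.1

    def test_overshoot_beyond_g1_field(self, bound_x):
        """Large |A3| pushes the outer g3-manifold line past B(g1)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lines = resonance_fields_perturbative(bound_x, [0, 0, 1],
                                                  include_nitrogens=False)
        b_g1 = resonance_field(bound_x.g.g1, bound_x.mw_frequency)
        assert max(b for b, a in lines if a > 0.05) > b_g1

    def test_perturbation_warning_for_extreme_coupling(self):
        huge = SpinSystem(GTensor(2.0, 2.0, 2.2),
                          CuHyperfine(2000, 2000, 2000, ("+", "+", "+")),
                          mw_frequency=9.3)
        with pytest.warns(UserWarning, match="perturbation parameter"):
            resonance_fields_perturbative(huge, [0, 0, 1])


@pytest.fixture(scope="module")
def bound_spectrum(request):
    systems = __import__("histbrace.pipeline", fromlist=["load_reference_systems"]
                         ).load_reference_systems()
    return simulate_powder(systems["chitin_X_14N"],
                           grid=orientation_grid(1.5))


class TestPowder:
    def test_axial_turning_points(self):
        """g1 = g2 system: derivative extrema at the g⊥ and g∥ edges."""
        axial = SpinSystem(GTensor(2.05, 2.05, 2.25),
                           CuHyperfine(0, 0, 0, ("+", "+", "+")),
                           linewidths=(0.5, 0.0), mw_frequency=9.3)
        spec = simulate_powder(axial, grid=orientation_grid(1.0))
        b_perp = resonance_field(2.05, 9.3)
        b_par = resonance_field(2.25, 9.3)
        absorption = spec.absorption
        # absorption rises at the parallel edge and peaks near perpendicular
        peak_field = spec.field_mt[np.argmax(spec.intensity)]
        assert abs(peak_field - b_perp) < 2.0
        onset = spec.field_mt[np.nonzero(absorption > 0.02 * absorption.max())[0][0]]
        assert abs(onset - b_par) < 3.0

    def test_integral_positive_and_grid_stable(self, bound_spectrum, bound_x):
        a1 = area(bound_spectrum)
        assert a1 > 0
        finer = simulate_powder(bound_x, grid=orientation_grid(0.75),
                                field_axis=bound_spectrum.field_mt)
        assert abs(area(finer) - a1) / a1 < 0.01

    def test_doubling_linewidths_preserves_area(self, bound_spectrum, bound_x):
        wide = dataclasses.replace(
            bound_x, linewidths=(2 * bound_x.linewidths[0],
                                 2 * bound_x.linewidths[1]))
        a_wide = area(simulate_powder(wide, grid=orientation_grid(1.5),
                                      field_axis=bound_spectrum.field_mt))
        assert a_wide == pytest.approx(area(bound_spectrum), rel=0.01)

    def test_area_linear_in_scale(self, bound_spectrum, bound_x):
        doubled = simulate_powder(bound_x, grid=orientation_grid(1.5),
                                  field_axis=bound_spectrum.field_mt,
                                  scale=2.0)
        assert area(doubled) == pytest.approx(2 * area(bound_spectrum),
                                              rel=1e-9)

    def test_rotation_of_tensor_frame_invariant(self, bound_x):
        from scipy.spatial.transform import Rotation
        g0 = orientation_grid(1.0, octant=False, spacing_phi_deg=2.0)
        R = Rotation.from_euler("zyz", [25, 40, 10], degrees=True).as_matrix()
        sa = simulate_powder(bound_x, grid=g0)
        sb = simulate_powder(bound_x, grid=g0.rotated(R),
                             field_axis=sa.field_mt)
        rel = np.linalg.norm(sa.intensity - sb.intensity) / \
            np.linalg.norm(sa.intensity)
        assert rel < 0.01

    def test_azimuthal_density_irrelevant_for_axial(self):
        axial = SpinSystem(GTensor(2.05, 2.05, 2.25),
                           CuHyperfine(50, 50, 500, ("+", "+", "-")),
                           linewidths=(0.5, 0.0), mw_frequency=9.3)
        coarse = simulate_powder(axial, grid=orientation_grid(1.0,
                                                              spacing_phi_deg=15))
        fine = simulate_powder(axial, grid=orientation_grid(1.0,
                                                            spacing_phi_deg=5),
                               field_axis=coarse.field_mt)
        rel = np.linalg.norm(coarse.intensity - fine.intensity) / \
            np.linalg.norm(fine.intensity)
        assert rel < 0.01

    def test_narrow_axis_rejected(self, bound_x):
        with pytest.raises(ValueError, match="does not span"):
            simulate_powder(bound_x, field_axis=np.linspace(300, 310, 64))

    def test_spectrum_io_round_trip(self, tmp_path, bound_spectrum):
        path = tmp_path / "spec.txt"
        write_spectrum(bound_spectrum, path)
        back = read_spectrum(path)
        assert np.allclose(back.field_mt, bound_spectrum.field_mt)
        assert np.allclose(back.intensity, bound_spectrum.intensity)
        assert back.mw_frequency == bound_spectrum.mw_frequency


class TestFit:
    def test_noiseless_self_fit_is_fixed_point(self, free_x):
        grid = orientation_grid(4.0)
        obs = simulate_powder(free_x, grid=grid)
        best, residual, diag = fit_spectrum(obs, free_x,
                                            free_params=["g3", "absA3"],
                                            grid=grid, maxiter=3)
        assert residual < 1e-3
        assert best.g.g3 == pytest.approx(free_x.g.g3, abs=1e-3)
        assert best.cuA.absA3 == pytest.approx(free_x.cuA.absA3, abs=0.5)

    def test_recovery_from_perturbed_start(self, bound_x):
        """Seeded noisy spectrum, 1%-off start: g3 and |A3| recovered."""
        from histbrace.synthetic import synth_spectrum
        grid = orientation_grid(4.0)
        obs = synth_spectrum(bound_x, snr=50.0, seed=11, grid=grid)
        start = dataclasses.replace(
            bound_x,
            g=GTensor(bound_x.g.g1 * 1.004, bound_x.g.g2 * 1.004,
                      bound_x.g.g3 * 1.01),
            cuA=CuHyperfine(bound_x.cuA.absA1 * 1.01,
                            bound_x.cuA.absA2 * 0.99,
                            bound_x.cuA.absA3 * 1.01, bound_x.cuA.signs))
        best, residual, diag = fit_spectrum(obs, start, grid=grid)
        assert abs(best.g.g3 - bound_x.g.g3) < 0.005
        assert abs(best.cuA.absA3 - bound_x.cuA.absA3) < 10.0

    def test_joint_x_q_sharpens_g2(self, reference_systems):
        """Adding a Q-band spectrum steepens the per-spectrum residual
        rise when g2 is displaced (tighter constraint than X alone)."""
        sys_x = reference_systems["free_X_14N"]
        sys_q = sys_x.with_frequency(35.0)
        grid = orientation_grid(4.0)
        spec_x = simulate_powder(sys_x, grid=grid)
        spec_q = simulate_powder(sys_q, grid=grid)

        def curvature(spectra):
            off = dataclasses.replace(sys_x, g=GTensor(sys_x.g.g1,
                                                       sys_x.g.g2 + 0.01,
                                                       sys_x.g.g3))
            total = 0.0
            for sp in spectra:
                sim = simulate_powder(off.with_frequency(sp.mw_frequency),
                                      grid=grid, field_axis=sp.field_mt)
                from histbrace.epr_forward import _residual
                total += _residual(sp, sim)
            return total / len(spectra)

        assert curvature([spec_x, spec_q]) > curvature([spec_x])

    def test_unknown_parameter_rejected(self, free_x):
        obs = simulate_powder(free_x, grid=orientation_grid(6.0))
        with pytest.raises(ValueError, match="unknown fit parameters"):
            fit_spectrum(obs, free_x, free_params=["gx"])
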