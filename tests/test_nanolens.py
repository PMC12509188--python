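"""Thermal-lens strength, closed-form signal, oracle agreement, lobes."""

import math

import numpy as np
import pytest

from thermopsf.beams import UM, peak_intensity
from thermopsf.nanolens import (
    AxialSignal,
    DetectionGeometry,
    axial_scan,
    curvature_term,
    delta_n,
    diffraction_oracle,
    lobe_analysis,
    phi_theta,
    phi_total,
    two_lobe_threshold,
)


class TestDeltaN:
    def test_peak_at_pump_focus_hand_value(self, scene):
        """Peak Δn equals σ I0 (dn/dT) / (4πκR) computed by hand."""
        i0 = peak_intensity(scene.drive, scene.pump)
        expected = (
            0.065e-12 * i0 * (-9e-7)
            / (4 * math.pi * 0.0262 * 0.25e-6)
        )
        got = float(delta_n(scene.with_parameters(focus_offset_um=3.0), 3.0))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got < 0  # air: dn/dT < 0

    def test_lorentzian_half_width_is_pump_rayleigh_range(self, scene):
        zrh = scene.pump.rayleigh_range_um
        peak = float(delta_n(scene, 0.0))
        assert float(delta_n(scene, zrh)) == pytest.approx(peak / 2.0, rel=1e-12)
        assert float(delta_n(scene, -zrh)) == pytest.approx(peak / 2.0, rel=1e-12)


class TestCurvatureTerm:
    def test_flat_at_waist(self, scene):
        z0 = complex(curvature_term(scene.probe, 0.0))
        assert z0.imag == 0.0
        assert z0.real == pytest.approx(1.0 / scene.probe.waist_um**2, rel=1e-14)

    def test_conjugate_antisymmetry(self, scene):
        zp = complex(curvature_term(scene.probe, 3.7))
        zm = complex(curvature_term(scene.probe, -3.7))
        assert zm == pytest.approx(zp.conjugate(), rel=1e-14)

    def test_rayleigh_range_identities(self, scene):
        zr = scene.probe.rayleigh_range_um
        zeta = complex(curvature_term(scene.probe, zr))
        assert zeta.real == pytest.approx(0.5 / scene.probe.waist_um**2, rel=1e-14)
        assert zeta.imag == pytest.approx(scene.probe.k_per_um / (4.0 * zr), rel=1e-14)


class TestPhiTheta:
    def test_null_absorber_exactly_zero(self, scene):
        null = scene.with_parameters(cross_section_um2=0.0)
        z = np.linspace(-10, 10, 41)
        for th in (0.0, 10.0, 25.0):
            assert np.all(phi_theta(null, th, z) == 0.0)

    def test_on_axis_reduction(self, scene):
        """At θ=0 the ₁F₁ argument vanishes and only the Γ factor remains."""
        z = 2.0
        dn = float(delta_n(scene, z))
        eta = scene.probe.k0_per_um * scene.bead_radius_um * dn
        zeta = complex(curvature_term(scene.probe, z))
        gamma2 = math.pi * eta / math.sinh(math.pi * eta)
        expected = math.exp(2 * eta * np.angle(zeta)) * gamma2 - 1.0
        assert float(phi_theta(scene, 0.0, z)) == pytest.approx(expected, rel=1e-12)

    def test_sign_flips_across_focus(self, scene):
        assert float(phi_theta(scene, 0.0, 1.0)) < 0 < float(phi_theta(scene, 0.0, -1.0))


class TestDiffractionOracle:
    @pytest.mark.parametrize("theta_deg", [5.0, 15.0, 25.0])
    @pytest.mark.parametrize("z_um", [-5.0, -1.0, 1.0, 5.0])
    def test_closed_form_matches_numerical_diffraction(self, scene, theta_deg, z_um):
        """Gamma/₁F₁ closed form vs direct Fresnel integral within 1%."""
        closed = float(phi_theta(scene, theta_deg, z_um))
        oracle = diffraction_oracle(scene, theta_deg, z_um)
        assert oracle == pytest.approx(closed, rel=0.01, abs=5e-7)

    def test_no_phase_means_no_signal(self, scene):
        assert diffraction_oracle(scene, 15.0, 2.0, include_phase=False) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_on_axis_sign_flip(self, scene):
        lo = diffraction_oracle(scene, 0.5, -2.0)
        hi = diffraction_oracle(scene, 0.5, 2.0)
        assert lo > 0 > hi


class TestPhiTotal:
    def test_null_absorber(self, scene, detection):
        null = scene.with_parameters(cross_section_um2=0.0)
        assert np.all(phi_total(null, detection, np.linspace(-20, 20, 11)) == 0.0)

    def test_linearity_in_cross_section(self, scene, detection):
        """Doubling σ_abs doubles Φ_tot within 0.5% in the weak-lens regime."""
        z = np.array([-3.0, -1.0, 2.0, 4.0])
        small = scene.with_parameters(cross_section_um2=0.0065)
        double = scene.with_parameters(cross_section_um2=0.013)
        r = phi_total(double, detection, z) / phi_total(small, detection, z)
        assert np.all(np.abs(r - 2.0) < 0.01)

    def test_lobe_symmetry_small_perturbation(self, scene, detection):
        """|Φ_tot| is even in z at Δz=0 up to O(RΔnk0) corrections."""
        weak = scene.with_parameters(cross_section_um2=0.0065, focus_offset_um=0.0)
        z = np.linspace(-10, 10, 201)
        v = np.abs(phi_total(weak, detection, z))
        assert np.max(np.abs(v - v[::-1])) / v.max() < 0.01

    def test_lobe_amplitudes_near_equal_at_zero_offset(self, scene, detection, z_grid):
        sig = axial_scan(scene.with_parameters(focus_offset_um=0.0), detection, z_grid)
        rep = lobe_analysis(sig, noise_floor=0.01)
        assert rep.n_lobes == 2
        assert rep.amplitude_ratio > 0.97
        assert rep.lobe_positions_um[0] == pytest.approx(-rep.lobe_positions_um[1], abs=0.2)

    def test_node_doubling_invariance(self, scene, detection):
        z = np.linspace(-10, 10, 41)
        a = phi_total(scene, detection, z, rtol=1e-8)
        b = phi_total(scene, detection, z, rtol=1e-11)
        assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 1e-6


class TestAxialScan:
    def test_grid_refinement_stability(self, scene, detection):
        coarse = axial_scan(scene, detection, np.linspace(-10, 10, 201))
        fine = axial_scan(scene, detection, np.linspace(-10, 10, 401))
        pc = coarse.z_axis_um[np.argmax(np.abs(coarse.values))]
        pf = fine.z_axis_um[np.argmax(np.abs(fine.values))]
        assert abs(pc - pf) <= 0.1  # coarse grid step

    def test_monotone_grid_required(self, scene, detection):
        with pytest.raises(ValueError):
            axial_scan(scene, detection, np.array([0.0, -1.0, 1.0]))


class TestLobeAnalysis:
    def test_pure_gaussian_has_one_lobe(self):
        z = np.linspace(-5, 5, 201)
        sig = AxialSignal(z, np.exp(-(z**2)))
        rep = lobe_analysis(sig)
        assert rep.n_lobes == 1
        assert rep.amplitude_ratio == 0.0

    def test_all_zero_signal(self):
        z = np.linspace(-5, 5, 201)
        assert lobe_analysis(AxialSignal(z, np.zeros_like(z))).n_lobes == 0

    def test_moderate_offset_keeps_two_lobes(self, scene, detection, z_grid):
        sig = axial_scan(scene.with_parameters(focus_offset_um=5.0), detection, z_grid)
        assert lobe_analysis(sig, noise_floor=0.01).n_lobes == 2

    def test_large_offset_single_then_no_lobe(self, scene, detection, z_grid):
        """Beyond the threshold the weak lobe sinks below the noise floor."""
        sig = axial_scan(scene.with_parameters(focus_offset_um=16.0), detection, z_grid)
        assert lobe_analysis(sig, noise_floor=0.01).n_lobes == 1
        sig = axial_scan(scene.with_parameters(focus_offset_um=25.0), detection, z_grid)
        assert lobe_analysis(sig, noise_floor=0.01).n_lobes == 0


class TestTwoLobeThreshold:
    def test_instrument_scene_threshold(self, scene, detection):
        thr = two_lobe_threshold(scene, detection, dz_step_um=0.5, refine_to_um=0.1)
        assert thr == pytest.approx(15.0, abs=2.0)

    def test_threshold_independent_of_cross_section_scale(self, scene, detection):
        """With a relative criterion the lobe shape is σ-independent."""
        z = np.linspace(-25, 25, 301)
        base = axial_scan(scene.with_parameters(focus_offset_um=8.0), detection, z)
        scaled = axial_scan(
            scene.with_parameters(cross_section_um2=0.0065, focus_offset_um=8.0),
            detection, z,
        )
        r1 = lobe_analysis(base, min_relative_amplitude=0.2, noise_floor=None)
        r2 = lobe_analysis(scaled, min_relative_amplitude=0.2, noise_floor=None)
        assert r1.n_lobes == r2.n_lobes
        assert r1.amplitude_ratio == pytest.approx(r2.amplitude_ratio, abs=0.05)

    def test_missing_transition_raises(self, scene, detection):
        with pytest.raises(ValueError):
            two_lobe_threshold(scene, detection, dz_max_um=2.0, refine_to_um=None)


class TestDetectionGeometry:
    def test_theta_max_from_numerical_aperture(self):
        det = DetectionGeometry.from_numerical_aperture(0.5, 1.0003, 21.0)
        assert det.theta_max_deg == pytest.approx(30.0, abs=0.05)

    def test_invalid_cone_rejected(self):
        with pytest.raises(ValueError):
            DetectionGeometry(30.0, 21.0)
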