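"""Rotation search, central-line extraction, Gaussian fits, ellipticity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from thermopsf.profiles import (
    GaussianFitResult,
    LineProfile,
    ScanImage,
    beam_ellipticity,
    central_line_profile,
    fit_gaussian,
    rotation_align,
)


def two_lobe_image(tilt_deg=0.0, noise_sd=0.0, seed=0, n=81):
    """Synthetic vertical two-lobe feature, optionally tilted and noisy."""
    ax = np.linspace(-4, 4, n)
    xx, zz = np.meshgrid(ax, ax)
    img = np.abs(zz) * np.exp(-(zz**2) / 4.0) * np.exp(-(xx**2) / 0.08)
    if tilt_deg:
        img = ndimage.rotate(img, tilt_deg, reshape=False, order=1)
    if noise_sd:
        img = img + noise_sd * np.random.default_rng(seed).standard_normal(img.shape)
    pitch = ax[1] - ax[0]
    return ScanImage(img, pitch, pitch)


class TestRotationAlign:
    def test_aligned_image_recovers_zero(self):
        _, angle = rotation_align(two_lobe_image(), angle_range_deg=5.0)
        assert abs(angle) <= 0.1

    def test_round_trip_recovers_tilt(self):
        _, angle = rotation_align(two_lobe_image(tilt_deg=3.0), angle_range_deg=5.0)
        assert angle == pytest.approx(-3.0, abs=0.2)

    def test_total_intensity_approximately_preserved(self):
        img = two_lobe_image(tilt_deg=3.0)
        rotated, _ = rotation_align(img, angle_range_deg=5.0)
        assert rotated.pixel_values.sum() == pytest.approx(
            img.pixel_values.sum(), rel=0.01
        )

    def test_idempotent_within_grid_step(self):
        rotated, _ = rotation_align(two_lobe_image(tilt_deg=3.0), angle_range_deg=5.0)
        _, second = rotation_align(rotated, angle_range_deg=5.0)
        assert abs(second) <= 0.2

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError):
            rotation_align(ScanImage(np.ones((10, 10)), 0.1, 0.1))


class TestCentralLineProfile:
    @staticmethod
    def separable(n=41):
        ax = np.linspace(-2, 2, n)
        xx, zz = np.meshgrid(ax, ax)
        img = np.exp(-(zz**2)) * np.exp(-(xx**2) / 0.5)
        return ScanImage(img, ax[1] - ax[0], ax[1] - ax[0])

    def test_single_line_is_exact_central_column(self):
        img = self.separable()
        prof = central_line_profile(img, axis="slow", n_lines=1)
        assert np.allclose(prof.intensity, img.pixel_values[:, 20])
        assert np.allclose(np.diff(prof.coordinate_um), img.pixel_pitch_slow_um)

    def test_three_lines_same_shape_for_separable_data(self):
        img = self.separable()
        p1 = central_line_profile(img, n_lines=1)
        p3 = central_line_profile(img, n_lines=3)
        s1 = p1.intensity / p1.intensity.max()
        s3 = p3.intensity / p3.intensity.max()
        assert np.max(np.abs(s1 - s3)) < 1e-6

    def test_averaging_reduces_noise(self):
        """Mean of 3 lines tracks the true profile better than 1 line."""
        ax = np.linspace(-2, 2, 41)
        truth = np.exp(-(ax**2))
        wins = 0
        for seed in range(100):
            img = self.separable()
            noisy = img.pixel_values + 0.1 * np.random.default_rng(seed).standard_normal(
                img.pixel_values.shape
            )
            noisy_img = ScanImage(noisy, img.pixel_pitch_fast_um, img.pixel_pitch_slow_um)
            r1 = central_line_profile(noisy_img, n_lines=1).intensity
            r3 = central_line_profile(noisy_img, n_lines=3).intensity
            e1 = np.sum((r1 / r1.max() - truth) ** 2)
            e3 = np.sum((r3 / r3.max() - truth) ** 2)
            wins += e3 < e1
        assert wins > 60

    def test_even_n_lines_rejected(self):
        with pytest.raises(ValueError):
            central_line_profile(self.separable(), n_lines=2)

    def test_border_maximum_flagged(self):
        v = np.zeros((11, 11))
        v[0, 5] = 1.0
        v += 0.001
        prof = central_line_profile(ScanImage(v, 0.1, 0.1), axis="slow")
        assert "warning" in prof.metadata


class TestFitGaussian:
    @staticmethod
    def gaussian_profile(fwhm=0.42, amp=1.0, center=0.0, offset=0.0, noise=0.0, seed=0):
        x = np.linspace(-1.5, 1.5, 121)
        y = amp * np.exp(-4 * math.log(2) * (x - center) ** 2 / fwhm**2) + offset
        if noise:
            y = y + noise * amp * np.random.default_rng(seed).standard_normal(x.size)
        return LineProfile(x, y)

    def test_noiseless_exact_recovery(self):
        res = fit_gaussian(self.gaussian_profile(fwhm=0.42, amp=2.0, offset=0.3))
        assert res.fwhm_um == pytest.approx(0.42, abs=1e-9)
        assert res.amplitude == pytest.approx(2.0, abs=1e-9)
        assert res.offset == pytest.approx(0.3, abs=1e-9)

    def test_noisy_mean_recovery_within_two_percent(self):
        fits = [
            fit_gaussian(self.gaussian_profile(noise=0.05, seed=s)).fwhm_um
            for s in range(100)
        ]
        assert np.mean(fits) == pytest.approx(0.42, rel=0.02)

    def test_scale_equivariance(self):
        prof = self.gaussian_profile(amp=1.3, offset=0.2)
        scaled = LineProfile(prof.coordinate_um, 7.0 * prof.intensity)
        a, b = fit_gaussian(prof), fit_gaussian(scaled)
        assert b.amplitude == pytest.approx(7.0 * a.amplitude, rel=1e-9)
        assert b.center_um == pytest.approx(a.center_um, abs=1e-9)
        assert b.fwhm_um == pytest.approx(a.fwhm_um, rel=1e-9)

    def test_monotone_ramp_fails_loudly(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises((RuntimeError, ValueError)):
            fit_gaussian(LineProfile(x, 10.0 * x))

    def test_errors_are_reported(self):
        res = fit_gaussian(self.gaussian_profile(noise=0.05, seed=3))
        assert isinstance(res, GaussianFitResult)
        assert res.fwhm_sd > 0 and res.center_sd > 0


class TestBeamEllipticity:
    def test_profiler_widths(self):
        assert round(beam_ellipticity(1.049, 1.059), 2) == 0.99

    def test_circular_beam(self):
        assert beam_ellipticity(2.0, 2.0) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_swap_gives_reciprocal(self, dx, dy):
        assert beam_ellipticity(dx, dy) * beam_ellipticity(dy, dx) == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            beam_ellipticity(0.0, 1.0)
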