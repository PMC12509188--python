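"""Synthetic bead-scan images with the structure the analysis assumes.

The generators emulate the two image types the processing pipeline consumes:
an x–z scan whose vertical structure is the axial photothermal signal
|Φ_tot(z)| with an approximately separable Gaussian radial envelope, and an
x–y spot image of a radially symmetric PSF.  Noise is additive Gaussian on
the (lock-in) amplitude, which is a good description at high signal-to-noise
ratio; a multiplicative option exists.  All generators are pure functions of
their parameters and the seed.

These images deliberately omit detector shot-noise statistics, stage drift
and ambient-light variation; they exercise the geometry and estimators, not
the detector physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nanolens import AxialSignal, DetectionGeometry, ThermalLensScene, phi_total
from .profiles import ScanImage

__all__ = ["NoiseSpec", "make_axial_image", "make_radial_image"]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive (or multiplicative) Gaussian noise: sd as a fraction of peak."""

    relative_sd: float = 0.0
    seed: int = 0
    multiplicative: bool = False

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("noise sd must be non-negative")


def _apply_noise(img: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.relative_sd == 0.0:
        return img
    rng = np.random.default_rng(noise.seed)
    scale = noise.relative_sd * float(np.max(np.abs(img)))
    draw = rng.standard_normal(img.shape)
    if noise.multiplicative:
        return img * (1.0 + noise.relative_sd * draw)
    return img + scale * draw


def make_axial_image(
    scene: ThermalLensScene,
    detection: DetectionGeometry,
    z_grid_um,
    x_grid_um,
    radial_width_um: float,
    tilt_deg: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
) -> ScanImage:
    """Synthetic x–z scan: |Φ_tot(z)| ⊗ Gaussian(x), tilted, noisy.

    ``radial_width_um`` is the FWHM of the radial envelope (use the
    theoretical radial PSF width).  ``tilt_deg`` rotates the image about its
    centre, emulating sample tilt / axis misalignment; the rotation-search
    pipeline should recover ``-tilt_deg``.  z maps to rows (slow axis), x to
    columns (fast axis).
    """
    z = np.asarray(z_grid_um, float)
    x = np.asarray(x_grid_um, float)
    for name, g in (("z_grid", z), ("x_grid", x)):
        if g.ndim != 1 or g.size < 3 or not np.all(np.diff(g) > 0):
            raise ValueError(f"{name} must be 1-D, strictly increasing, length >= 3")
    if not radial_width_um > 0:
        raise ValueError("radial width must be positive")
    axial = np.abs(phi_total(scene, detection, z))
    envelope = np.exp(-4.0 * math.log(2.0) * (x - x.mean()) ** 2 / radial_width_um**2)
    img = np.outer(axial, envelope)
    if tilt_deg != 0.0:
        img = ndimage.rotate(
            img, tilt_deg, reshape=False, order=1, mode="constant", cval=float(img.min())
        )
    img = _apply_noise(img, noise)
    return ScanImage(
        img,
        pixel_pitch_fast_um=float(np.diff(x).mean()),
        pixel_pitch_slow_um=float(np.diff(z).mean()),
        axes_labels=("x", "z"),
        metadata={
            "kind": "synthetic_axial",
            "tilt_deg": tilt_deg,
            "noise": noise,
            "radial_width_um": radial_width_um,
        },
    )


def make_radial_image(
    fwhm_um: float,
    pixel_pitch_um: float,
    extent_um: float,
    noise: NoiseSpec = NoiseSpec(),
) -> ScanImage:
    """Synthetic x–y spot: radially symmetric Gaussian of the given FWHM.

    ``extent_um`` is the full side length of the square image and must be at
    least three times the FWHM so the fit sees the wings.
    """
    if not fwhm_um > 0 or not pixel_pitch_um > 0:
        raise ValueError("fwhm and pixel pitch must be positive")
    if extent_um < 3.0 * fwhm_um:
        raise ValueError("extent must be at least 3x the FWHM")
    n = int(round(extent_um / pixel_pitch_um)) + 1
    ax = (np.arange(n) - (n - 1) / 2.0) * pixel_pitch_um
    xx, yy = np.meshgrid(ax, ax)
    img = np.exp(-4.0 * math.log(2.0) * (xx**2 + yy**2) / fwhm_um**2)
    img = _apply_noise(img, noise)
    return ScanImage(
        img,
        pixel_pitch_fast_um=pixel_pitch_um,
        pixel_pitch_slow_um=pixel_pitch_um,
        axes_labels=("x", "y"),
        metadata={"kind": "synthetic_radial", "fwhm_um": fwhm_um, "noise": noise},
    )
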