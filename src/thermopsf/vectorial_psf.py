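"""Vectorial field integrals and confocal point-spread functions.

For an aplanatic objective focusing linearly polarised light, the field near
focus is built from three one-dimensional aperture-angle integrals

.. math::

    e_0 = \\int_{\\theta_{min}}^{\\alpha} P(\\theta)\\,(1+\\cos\\theta)\\,
          J_0(k r \\sin\\theta)\\, e^{-i k z \\cos\\theta} \\sin\\theta\\,
          d\\theta,

with :math:`e_1` (weight :math:`\\sin^2\\theta`, :math:`J_1`) and :math:`e_2`
(weight :math:`(1-\\cos\\theta)\\sin\\theta`, :math:`J_2`) analogous,
:math:`k = 2\\pi n/\\lambda` and :math:`\\alpha = \\arcsin(NA/n)` the maximum
aperture angle.  A reflective (Schwarzschild) objective with a central
obscuration has a nonzero minimum angle :math:`\\theta_{min}`.

For small apertures only :math:`e_0` survives, the focal field is radially
symmetric, and the intensity PSF is :math:`|e_0|^2`; that low-aperture form
is the default here because the resolution figures it produces match the
instruments modelled.  The full vectorial sum
:math:`|e_0|^2 + 2|e_1|^2 + |e_2|^2` is available as an option.  A confocal
microscope multiplies the illumination- and collection-arm intensities
pointwise.

Apodization models: ``"uniform"`` (P = 1, default), ``"cosine"``
(P = cos θ) and ``"sqrt_cosine"`` (P = √cos θ, the Abbe-sine aplanatic
factor).  The default is the one that reproduces the instruments' quoted
confocal FWHM values; see ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j0, j1, jn

from .profiles import LineProfile

__all__ = [
    "APODIZATIONS",
    "ObjectiveSpec",
    "FieldComponents",
    "IntensityGrid",
    "field_components",
    "intensity_psf",
    "confocal_psf",
    "radial_profile",
    "axial_profile",
    "fwhm_of_profile",
]

APODIZATIONS = ("uniform", "cosine", "sqrt_cosine")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Aperture geometry and apodization of one focusing or collection arm.

    ``theta_min_deg`` is the half-angle of a central obscuration (0 for a
    full aperture).  The maximum aperture angle α = arcsin(NA/n) must exceed
    it.
    """

    numerical_aperture: float
    theta_min_deg: float = 0.0
    medium_index: float = 1.0
    apodization: str = "uniform"

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture < self.medium_index:
            raise ValueError(
                f"need 0 < NA < n, got NA={self.numerical_aperture}, n={self.medium_index}"
            )
        if self.apodization not in APODIZATIONS:
            raise ValueError(
                f"unknown apodization {self.apodization!r}; choose from {APODIZATIONS}"
            )
        if not 0 <= self.theta_min_deg < math.degrees(self.alpha_rad):
            raise ValueError(
                f"theta_min={self.theta_min_deg} deg must satisfy "
                f"0 <= theta_min < alpha={math.degrees(self.alpha_rad):.3f} deg"
            )

    @property
    def alpha_rad(self) -> float:
        """Maximum aperture angle arcsin(NA/n) in radians."""
        return math.asin(self.numerical_aperture / self.medium_index)

    @property
    def theta_min_rad(self) -> float:
        return math.radians(self.theta_min_deg)


@dataclass(frozen=True)
class FieldComponents:
    """Complex field components e0, e1, e2 on a common (r, z) sampling."""

    e0: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    def intensity(self, vectorial: bool = False) -> np.ndarray:
        """|e0|² (default) or the full vectorial sum |e0|²+2|e1|²+|e2|²."""
        if vectorial:
            return (
                np.abs(self.e0) ** 2
                + 2.0 * np.abs(self.e1) ** 2
                + np.abs(self.e2) ** 2
            )
        return np.abs(self.e0) ** 2


@dataclass(frozen=True)
class IntensityGrid:
    """Peak-normalised nonnegative intensity on an (r >= 0, z) grid.

    ``values[i, j]`` corresponds to ``(z_axis_um[i], r_axis_um[j])``.
    """

    r_axis_um: np.ndarray
    z_axis_um: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r_axis_um, float)
        z = np.asarray(self.z_axis_um, float)
        v = np.asarray(self.values, float)
        object.__setattr__(self, "r_axis_um", r)
        object.__setattr__(self, "z_axis_um", z)
        object.__setattr__(self, "values", v)
        if np.any(r < 0):
            raise ValueError("radial axis must be non-negative")
        if v.shape != (z.size, r.size):
            raise ValueError(f"values shape {v.shape} != (nz, nr) = {(z.size, r.size)}")
        if np.any(v < 0):
            raise ValueError("intensity must be non-negative")

    def radial_profile(self, mirror: bool = True) -> LineProfile:
        """Profile along r at the z of the global maximum (mirrored to ±r)."""
        iz = int(np.argmax(self.values.max(axis=1)))
        return _mirror_profile(self.r_axis_um, self.values[iz], mirror)

    def axial_profile(self) -> LineProfile:
        """On-axis (r = min r) profile along z."""
        return LineProfile(self.z_axis_um, self.values[:, 0])


def _mirror_profile(r: np.ndarray, v: np.ndarray, mirror: bool) -> LineProfile:
    if mirror and r[0] == 0.0:
        x = np.concatenate([-r[:0:-1], r])
        y = np.concatenate([v[:0:-1], v])
        return LineProfile(x, y)
    return LineProfile(r, v)


def _apodization_values(objective: ObjectiveSpec, theta: np.ndarray) -> np.ndarray:
    if objective.apodization == "uniform":
        return np.ones_like(theta)
    if objective.apodization == "cosine":
        return np.cos(theta)
    return np.sqrt(np.cos(theta))


def _aperture_integrals(
    objective: ObjectiveSpec,
    wavelength_um: float,
    r_um: np.ndarray,
    z_um: np.ndarray,
    nodes: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gauss–Legendre evaluation of the three field integrals at fixed nodes.

    ``r_um`` and ``z_um`` must be broadcast to a common flat shape.
    """
    a, b = objective.theta_min_rad, objective.alpha_rad
    x, w = leggauss(nodes)
    th = 0.5 * (b - a) * x + 0.5 * (b + a)
    w = 0.5 * (b - a) * w
    k = 2.0 * math.pi * objective.medium_index / wavelength_um
    p = _apodization_values(objective, th)
    sin_t, cos_t = np.sin(th), np.cos(th)
    kr = k * np.multiply.outer(r_um, sin_t)  # (npts, nodes)
    phase = np.exp(-1j * k * np.multiply.outer(z_um, cos_t))
    e0 = (p * (1.0 + cos_t) * sin_t * w * j0(kr) * phase).sum(axis=-1)
    e1 = (p * sin_t**2 * w * j1(kr) * phase).sum(axis=-1)
    e2 = (p * (1.0 - cos_t) * sin_t * w * jn(2, kr) * phase).sum(axis=-1)
    return e0, e1, e2


def field_components(
    objective: ObjectiveSpec,
    wavelength_um: float,
    r_um,
    z_um,
    rtol: float = 1e-8,
    max_nodes: int = 4096,
) -> FieldComponents:
    """Evaluate e0, e1, e2 at positions (r, z), broadcast against each other.

    The aperture integrals are evaluated with Gauss–Legendre quadrature whose
    node count is doubled until the result changes by less than ``rtol`` in a
    global relative sense.  Non-convergence raises with the achieved
    tolerance.
    """
    if not wavelength_um > 0:
        raise ValueError("wavelength must be positive")
    r_b, z_b = np.broadcast_arrays(
        np.asarray(r_um, float), np.asarray(z_um, float)
    )
    shape = r_b.shape
    r_f, z_f = np.abs(r_b).ravel(), z_b.ravel()
    if not (np.all(np.isfinite(r_f)) and np.all(np.isfinite(z_f))):
        raise ValueError("positions must be finite")

    nodes = 64
    prev = _aperture_integrals(objective, wavelength_um, r_f, z_f, nodes)
    achieved = math.inf
    while nodes < max_nodes:
        nodes *= 2
        cur = _aperture_integrals(objective, wavelength_um, r_f, z_f, nodes)
        scale = max(float(np.max(np.abs(cur[0]))), 1e-300)
        achieved = max(
            float(np.max(np.abs(c - p))) / scale for c, p in zip(cur, prev)
        )
        prev = cur
        if achieved <= rtol:
            break
    else:
        raise RuntimeError(
            f"aperture quadrature did not converge: achieved {achieved:.2e} "
            f"with {nodes} nodes (requested rtol={rtol:.2e})"
        )
    e0, e1, e2 = (c.reshape(shape) for c in prev)
    return FieldComponents(e0, e1, e2)


def intensity_psf(
    objective: ObjectiveSpec,
    wavelength_um: float,
    r_axis_um,
    z_axis_um,
    vectorial: bool = False,
) -> IntensityGrid:
    """Peak-normalised single-arm intensity PSF on an (r, z) grid.

    The map is radially symmetric by construction (only r >= 0 is sampled);
    2-D x–y or x–z images are obtained by mirroring.
    """
    r = np.asarray(r_axis_um, float)
    z = np.asarray(z_axis_um, float)
    _require_monotone(r, "r_axis"), _require_monotone(z, "z_axis")
    fc = field_components(objective, wavelength_um, r[None, :], z[:, None])
    vals = fc.intensity(vectorial)
    peak = vals.max()
    if peak <= 0:
        raise ValueError("PSF is identically zero on the requested grid")
    return IntensityGrid(
        r, z, vals / peak,
        metadata={"objective": objective, "wavelength_um": wavelength_um,
                  "vectorial": vectorial},
    )


def confocal_psf(
    illumination: ObjectiveSpec,
    collection: ObjectiveSpec,
    wavelength_um: float,
    r_axis_um,
    z_axis_um,
    vectorial: bool = False,
) -> IntensityGrid:
    """Confocal PSF: pointwise product of the two arm intensities, peak 1.

    For a reflection confocal microscope both arms are the same objective;
    for a transmission instrument they may differ (e.g. one annular arm).
    """
    r = np.asarray(r_axis_um, float)
    z = np.asarray(z_axis_um, float)
    _require_monotone(r, "r_axis"), _require_monotone(z, "z_axis")
    fi = field_components(illumination, wavelength_um, r[None, :], z[:, None])
    fc = field_components(collection, wavelength_um, r[None, :], z[:, None])
    vals = fi.intensity(vectorial) * fc.intensity(vectorial)
    peak = vals.max()
    if peak <= 0:
        raise ValueError("confocal PSF is identically zero on the requested grid")
    return IntensityGrid(
        r, z, vals / peak,
        metadata={"illumination": illumination, "collection": collection,
                  "wavelength_um": wavelength_um, "vectorial": vectorial},
    )


def radial_profile(
    illumination: ObjectiveSpec,
    collection: ObjectiveSpec | None,
    wavelength_um: float,
    r_max_um: float = 1.5,
    n: int = 1501,
) -> LineProfile:
    """Radial confocal (or single-arm) intensity profile at z = 0, mirrored."""
    r = np.linspace(0.0, r_max_um, n)
    fi = field_components(illumination, wavelength_um, r, 0.0 * r)
    vals = fi.intensity()
    if collection is not None:
        vals = vals * field_components(collection, wavelength_um, r, 0.0 * r).intensity()
    vals = vals / vals.max()
    return _mirror_profile(r, vals, mirror=True)


def axial_profile(
    illumination: ObjectiveSpec,
    collection: ObjectiveSpec | None,
    wavelength_um: float,
    z_max_um: float = 8.0,
    n: int = 2001,
) -> LineProfile:
    """On-axis confocal (or single-arm) intensity profile along z."""
    z = np.linspace(-z_max_um, z_max_um, n)
    fi = field_components(illumination, wavelength_um, 0.0 * z, z)
    vals = fi.intensity()
    if collection is not None:
        vals = vals * field_components(collection, wavelength_um, 0.0 * z, z).intensity()
    vals = vals / vals.max()
    return LineProfile(z, vals)


def fwhm_of_profile(profile: LineProfile) -> float:
    """Full width at half maximum of a single-peaked profile, in μm.

    The two half-maximum crossings are located by linear interpolation on the
    monotone flanks adjacent to the global maximum.  A profile that does not
    cross half maximum on one side raises an error naming the side.
    """
    x, y = profile.coordinate_um, profile.intensity
    i = int(np.argmax(y))
    top = float(y[i])
    base = 0.0
    half = base + (top - base) / 2.0

    def crossing(left: bool) -> float:
        if left:
            seg = np.nonzero(y[: i + 1] < half)[0]
            if seg.size == 0:
                raise ValueError("profile does not cross half maximum on the left side")
            a = int(seg[-1])
            b = a + 1
        else:
            seg = np.nonzero(y[i:] < half)[0]
            if seg.size == 0:
                raise ValueError("profile does not cross half maximum on the right side")
            b = i + int(seg[0])
            a = b - 1
        ya, yb = float(y[a]), float(y[b])
        if yb == ya:
            return float(x[a])
        return float(x[a]) + (half - ya) * (float(x[b]) - float(x[a])) / (yb - ya)

    return crossing(left=False) - crossing(left=True)


def _require_monotone(axis: np.ndarray, name: str) -> None:
    if axis.ndim != 1 or axis.size < 1 or not np.all(np.diff(axis) > 0):
        raise ValueError(f"{name} must be 1-D and strictly increasing")
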