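"""Scan-image and line-profile processing.

Implements the measurement-side pipeline used to turn bead scans into
resolution figures: a brute-force rotation search that aligns tilted x–z
scans with the vertical axis, extraction of the mean of a few central lines,
Gaussian fits with parameter uncertainties, and the second-moment beam
ellipticity ratio.

Images are stored row-major with the slow axis (y or z) as rows; physical
coordinates originate at the image centre.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "ScanImage",
    "LineProfile",
    "GaussianFitResult",
    "rotation_align",
    "central_line_profile",
    "fit_gaussian",
    "beam_ellipticity",
]


@dataclass(frozen=True)
class LineProfile:
    """A 1-D sampled signal: strictly increasing coordinate (μm) + intensity."""

    coordinate_um: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.coordinate_um, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "coordinate_um", x)
        object.__setattr__(self, "intensity", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("coordinate and intensity must be 1-D and equal length")
        if x.size < 5:
            raise ValueError(f"profile needs at least 5 samples, got {x.size}")
        if not np.all(np.diff(x) > 0):
            raise ValueError("coordinate must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensity contains non-finite values")


@dataclass(frozen=True)
class ScanImage:
    """A 2-D scan: slow axis (y or z) along rows, fast axis (x) along columns.

    ``pixel_pitch_fast_um`` is the column spacing, ``pixel_pitch_slow_um`` the
    row spacing.  ``axes_labels`` names (fast, slow), e.g. ``("x", "z")``.
    """

    pixel_values: np.ndarray
    pixel_pitch_fast_um: float
    pixel_pitch_slow_um: float
    axes_labels: tuple[str, str] = ("x", "z")
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.pixel_values, dtype=float)
        object.__setattr__(self, "pixel_values", v)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] < 3:
            raise ValueError(f"image must be 2-D with at least 3x3 pixels, got {v.shape}")
        if not (self.pixel_pitch_fast_um > 0 and self.pixel_pitch_slow_um > 0):
            raise ValueError("pixel pitches must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")

    def fast_axis_um(self) -> np.ndarray:
        n = self.pixel_values.shape[1]
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch_fast_um

    def slow_axis_um(self) -> np.ndarray:
        n = self.pixel_values.shape[0]
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch_slow_um


@dataclass(frozen=True)
class GaussianFitResult:
    """Least-squares Gaussian fit: value ± one standard deviation each."""

    amplitude: float
    amplitude_sd: float
    center_um: float
    center_sd: float
    fwhm_um: float
    fwhm_sd: float
    offset: float
    offset_sd: float
    metadata: dict = field(default_factory=dict, compare=False)


def rotation_align(
    image: ScanImage,
    angle_range_deg: float = 15.0,
    angle_step_deg: float = 0.1,
) -> tuple[ScanImage, float]:
    """Rotate the image so the feature of interest lies along the vertical axis.

    Searches a grid of rotation angles in ``[-angle_range_deg,
    +angle_range_deg]`` and picks the angle maximising the peak of the
    column-summed intensity, i.e. the rotation that concentrates the most
    intensity along the vertical (slow) axis.  Rotation uses bilinear
    interpolation about the geometric image centre; pixels rotated in from
    outside are filled with the image minimum so the background offset is not
    biased toward zero.

    Returns the rotated image and the selected angle in degrees.
    """
    v = image.pixel_values
    if np.ptp(v) == 0:
        raise ValueError("cannot align a flat image")
    angles = np.arange(-angle_range_deg, angle_range_deg + angle_step_deg / 2, angle_step_deg)
    fill = float(v.min())

    def score(angle: float) -> float:
        rot = ndimage.rotate(v, angle, reshape=False, order=1, mode="constant", cval=fill)
        return float(rot.sum(axis=0).max())

    scores = [score(a) for a in angles]
    best = float(angles[int(np.argmax(scores))])
    rotated = ndimage.rotate(v, best, reshape=False, order=1, mode="constant", cval=fill)
    meta = dict(image.metadata)
    meta["rotation_applied_deg"] = best
    return (
        ScanImage(
            rotated,
            image.pixel_pitch_fast_um,
            image.pixel_pitch_slow_um,
            image.axes_labels,
            meta,
        ),
        best,
    )


def central_line_profile(
    image: ScanImage, axis: str = "slow", n_lines: int = 3
) -> LineProfile:
    """Mean of ``n_lines`` lines straddling the brightest line of the image.

    ``axis`` selects the direction of the returned profile: ``"slow"`` gives a
    profile along the slow (row) axis, averaging over the ``n_lines`` columns
    centred on the global-maximum column; ``"fast"`` the transpose.  The
    coordinate is physical (μm, from the pixel pitch, origin at the image
    centre).  A maximum on the image border is recorded as a warning in the
    profile metadata rather than raised.
    """
    if n_lines < 1 or n_lines % 2 == 0:
        raise ValueError(f"n_lines must be odd and >= 1, got {n_lines}")
    if axis not in ("fast", "slow"):
        raise ValueError(f"axis must be 'fast' or 'slow', got {axis!r}")
    v = image.pixel_values
    iy, ix = np.unravel_index(int(np.argmax(v)), v.shape)
    meta: dict = {"axis": axis, "n_lines": n_lines}

    if axis == "slow":
        coord = image.slow_axis_um()
        center, extent = ix, v.shape[1]
        half = n_lines // 2
        lo, hi = center - half, center + half + 1
        if lo < 0 or hi > extent:
            raise ValueError(f"n_lines={n_lines} does not fit around column {center}")
        values = v[:, lo:hi].mean(axis=1)
        if iy in (0, v.shape[0] - 1):
            meta["warning"] = "profile maximum lies on the image border"
    else:
        coord = image.fast_axis_um()
        center, extent = iy, v.shape[0]
        half = n_lines // 2
        lo, hi = center - half, center + half + 1
        if lo < 0 or hi > extent:
            raise ValueError(f"n_lines={n_lines} does not fit around row {center}")
        values = v[lo:hi, :].mean(axis=0)
        if ix in (0, v.shape[1] - 1):
            meta["warning"] = "profile maximum lies on the image border"
    return LineProfile(coord, values, meta)


def _gauss(x: np.ndarray, amplitude: float, center: float, fwhm: float, offset: float) -> np.ndarray:
    return amplitude * np.exp(-4.0 * math.log(2.0) * (x - center) ** 2 / fwhm**2) + offset


def fit_gaussian(profile: LineProfile) -> GaussianFitResult:
    """Nonlinear least-squares Gaussian fit of a line profile.

    Model: ``A exp(-4 ln2 (x-c)²/w²) + b`` with ``w`` the FWHM.  Initial
    guesses: ``A = max-min``, ``c = argmax``, ``w`` from the direct half-max
    width of the data (falling back to a quarter of the span when the data
    never cross half max), ``b = min``.  Parameter standard deviations come
    from the fit covariance.
    """
    x, y = profile.coordinate_um, profile.intensity
    y_min, y_max = float(y.min()), float(y.max())
    if y_max <= y_min:
        raise ValueError("profile has no discernible peak (constant intensity)")
    a0 = y_max - y_min
    c0 = float(x[int(np.argmax(y))])
    above = y - y_min > a0 / 2.0
    if above.any():
        idx = np.nonzero(above)[0]
        w0 = float(x[idx[-1]] - x[idx[0]])
    else:
        w0 = 0.0
    if w0 <= 0:
        w0 = float((x[-1] - x[0]) / 4.0)
    p0 = (a0, c0, w0, y_min)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # zero-residual fits trigger scipy's covariance warning; the
            # covariance is rebuilt below in that case
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(_gauss, x, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian fit did not converge (initial guesses amplitude={a0:g}, "
            f"center={c0:g} um, fwhm={w0:g} um, offset={y_min:g}): {exc}"
        ) from exc
    span = float(x[-1] - x[0])
    if not (x[0] - span <= popt[1] <= x[-1] + span) or abs(popt[2]) > 10.0 * span:
        raise RuntimeError(
            f"Gaussian fit degenerate: center {popt[1]:g} um / fwhm "
            f"{abs(popt[2]):g} um lie far outside the sampled range "
            f"(initial guesses amplitude={a0:g}, center={c0:g}, fwhm={w0:g}, "
            f"offset={y_min:g}); the profile has no resolvable peak"
        )
    if not np.all(np.isfinite(pcov)):
        # perfect (zero-residual) fits can leave MINPACK's covariance
        # undefined; rebuild it from a finite-difference jacobian
        jac = optimize.approx_fprime(
            popt, lambda p: _gauss(x, *p), np.full(4, 1e-8)
        )
        resid = _gauss(x, *popt) - y
        dof = max(x.size - 4, 1)
        s2 = float(resid @ resid) / dof
        try:
            pcov = s2 * np.linalg.inv(jac.T @ jac)
        except np.linalg.LinAlgError:
            pcov = np.full((4, 4), np.nan)
    with np.errstate(invalid="ignore"):
        sd = np.sqrt(np.abs(np.diag(pcov)))
    return GaussianFitResult(
        amplitude=float(popt[0]),
        amplitude_sd=float(sd[0]),
        center_um=float(popt[1]),
        center_sd=float(sd[1]),
        fwhm_um=abs(float(popt[2])),
        fwhm_sd=float(sd[2]),
        offset=float(popt[3]),
        offset_sd=float(sd[3]),
        metadata={"initial_guess": p0},
    )


def beam_ellipticity(width_x: float, width_y: float) -> float:
    """Beam ellipticity ε = D_x / D_y from two second-moment beam widths.

    ε = 1 is a perfectly circular beam; the widths may be in any common unit.
    """
    if not (width_x > 0 and width_y > 0):
        raise ValueError("beam widths must be positive")
    return width_x / width_y
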