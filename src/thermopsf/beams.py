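"""Gaussian-beam propagation and photothermal power/heat bookkeeping.

Conventions
-----------
* Lengths at the public surface are micrometres; powers are watts unless a
  name says otherwise; intensities are SI (W m^-2).
* ``z`` is the propagation coordinate with the waist at ``z = 0``; positive
  ``z`` lies downstream.  The radius of curvature follows the convention
  ``R_c(z) = z (1 + z_R^2/z^2)``: positive (diverging wavefronts) after the
  waist, negative before it.
* At the waist the wavefront is flat.  ``beam_radius_and_curvature`` reports
  that case as ``math.inf`` with the sign of approach left to the caller;
  downstream arithmetic should use :func:`inverse_curvature_radius`, which is
  smooth (``1/R_c = z / (z^2 + z_R^2)``) and exactly zero at the waist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GaussianBeamSpec",
    "PumpDriveSpec",
    "MediumSpec",
    "AIR_294K",
    "rayleigh_range",
    "beam_radius_and_curvature",
    "inverse_curvature_radius",
    "peak_intensity",
    "thermal_diffusion_length",
    "waist_from_fwhm",
    "fwhm_of_waist",
    "steady_state_check",
]

UM = 1e-6  # metres per micrometre


@dataclass(frozen=True)
class GaussianBeamSpec:
    """A TEM00 Gaussian beam: wavelength and waist radius in μm, medium index.

    The waist radius ``waist_um`` is the 1/e^2 intensity radius ω0.  The
    Rayleigh range ``z_R = π ω0² / λ`` and the wavenumbers ``k0 = 2π/λ``
    (vacuum) and ``k = n0 k0`` follow from the fields.
    """

    wavelength_um: float
    waist_um: float
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        if not self.wavelength_um > 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength_um}")
        if not self.waist_um > 0:
            raise ValueError(f"waist radius must be positive, got {self.waist_um}")
        if self.medium_index < 1:
            raise ValueError(f"medium index must be >= 1, got {self.medium_index}")

    @property
    def rayleigh_range_um(self) -> float:
        return math.pi * self.waist_um**2 / self.wavelength_um

    @property
    def k0_per_um(self) -> float:
        """Vacuum wavenumber 2π/λ in rad/μm."""
        return 2.0 * math.pi / self.wavelength_um

    @property
    def k_per_um(self) -> float:
        """Wavenumber in the medium, n0·2π/λ, in rad/μm."""
        return self.medium_index * self.k0_per_um


@dataclass(frozen=True)
class PumpDriveSpec:
    """Modulated pump-laser drive.

    ``average_power_W`` is the time-averaged optical power; ``duty_cycle`` is
    the on-fraction β of the modulation period, so the on-state peak power is
    ``P_max = P_avg / β``; ``modulation_frequency_Hz`` is the (ordinary)
    modulation frequency f; the angular frequency used in thermal-diffusion
    formulas is Ω = 2π f.
    """

    average_power_W: float
    duty_cycle: float
    modulation_frequency_Hz: float

    def __post_init__(self) -> None:
        if self.average_power_W < 0:
            raise ValueError("average power must be non-negative")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError(f"duty cycle must be in (0, 1], got {self.duty_cycle}")
        if not self.modulation_frequency_Hz > 0:
            raise ValueError("modulation frequency must be positive")

    @property
    def peak_power_W(self) -> float:
        return self.average_power_W / self.duty_cycle


@dataclass(frozen=True)
class MediumSpec:
    """Thermal and optical properties of the embedding medium (SI units)."""

    thermal_conductivity: float  # κ, W m^-1 K^-1
    specific_heat_capacity: float  # C_p, J kg^-1 K^-1
    density: float  # ρ, kg m^-3
    refractive_index: float = 1.0  # n0
    thermo_optic_coefficient: float = 0.0  # dn/dT, K^-1

    def __post_init__(self) -> None:
        for name in ("thermal_conductivity", "specific_heat_capacity", "density"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")


#: Dry air at 294 K.  κ and n0 are instrument-table values; C_p and ρ are
#: standard dry-air properties at that temperature.
AIR_294K = MediumSpec(
    thermal_conductivity=0.0262,
    specific_heat_capacity=1006.0,
    density=1.204,
    refractive_index=1.0003,
    thermo_optic_coefficient=-9e-7,
)


def rayleigh_range(beam: GaussianBeamSpec) -> float:
    """Rayleigh range z_R = π ω0²/λ in μm."""
    return beam.rayleigh_range_um


def beam_radius_and_curvature(beam: GaussianBeamSpec, z_um: float) -> tuple[float, float]:
    """Beam radius ω(z) and wavefront radius of curvature R_c(z), both μm.

    ``ω(z) = ω0 √(1 + z²/z_R²)`` and ``R_c(z) = z (1 + z_R²/z²)``.  At the
    waist the wavefront is flat and ``R_c`` is reported as ``math.inf``;
    arithmetic consumers should call :func:`inverse_curvature_radius` instead,
    which is finite everywhere.
    """
    zr = beam.rayleigh_range_um
    w = beam.waist_um * math.sqrt(1.0 + (z_um / zr) ** 2)
    if z_um == 0.0:
        return w, math.inf
    return w, z_um * (1.0 + (zr / z_um) ** 2)


def inverse_curvature_radius(beam: GaussianBeamSpec, z_um: float) -> float:
    """1/R_c(z) = z / (z² + z_R²) in μm^-1 — smooth, zero at the waist."""
    zr = beam.rayleigh_range_um
    return z_um / (z_um**2 + zr**2)


def peak_intensity(drive: PumpDriveSpec, pump: GaussianBeamSpec) -> float:
    """On-axis peak intensity I_0 = 2 P_max / (π ω0²) in W m^-2.

    ``P_max = P_avg/β`` is the on-state power of the modulated pump and ω0 the
    waist radius of the focused pump beam.
    """
    w0_m = pump.waist_um * UM
    return 2.0 * drive.peak_power_W / (math.pi * w0_m**2)


def thermal_diffusion_length(medium: MediumSpec, f_mod_Hz: float) -> float:
    """Thermal diffusion length R_th = sqrt(2κ / (C_p ρ Ω)) in μm.

    Ω = 2π f is the angular modulation frequency of the pump.  R_th is the
    penetration depth of the periodic temperature field; the steady-state
    treatment of the thermal lens holds while R_th exceeds the probe spot
    radius.
    """
    if not f_mod_Hz > 0:
        raise ValueError("modulation frequency must be positive")
    omega = 2.0 * math.pi * f_mod_Hz
    r_m = math.sqrt(
        2.0
        * medium.thermal_conductivity
        / (medium.specific_heat_capacity * medium.density * omega)
    )
    return r_m / UM


_FWHM_PER_WAIST = math.sqrt(2.0 * math.log(2.0))  # ≈ 1.1774


def waist_from_fwhm(fwhm_um: float) -> float:
    """1/e² waist radius ω0 of a Gaussian intensity profile with given FWHM.

    For ``I(r) = exp(-2 r²/ω0²)`` the full width at half maximum is
    ``ω0 √(2 ln 2)``, hence ``ω0 = FWHM / √(2 ln 2)``.
    """
    if not fwhm_um > 0:
        raise ValueError(f"FWHM must be positive, got {fwhm_um}")
    return fwhm_um / _FWHM_PER_WAIST


def fwhm_of_waist(waist_um: float) -> float:
    """Inverse of :func:`waist_from_fwhm`."""
    if not waist_um > 0:
        raise ValueError(f"waist must be positive, got {waist_um}")
    return waist_um * _FWHM_PER_WAIST


def steady_state_check(
    medium: MediumSpec, f_mod_Hz: float, probe_spot_radius_um: float
) -> tuple[bool, float]:
    """Whether R_th strictly exceeds the probe spot radius, and their ratio."""
    if not probe_spot_radius_um > 0:
        raise ValueError("probe spot radius must be positive")
    r_th = thermal_diffusion_length(medium, f_mod_Hz)
    ratio = r_th / probe_spot_radius_um
    return ratio > 1.0, ratio
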