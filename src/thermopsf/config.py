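"""Strictly validated TOML configuration for the instrument parameter set.

A configuration file mirrors the instrument table: sections ``[probe_beam]``,
``[pump_beam]``, ``[pump_drive]``, ``[medium]``, ``[absorber]``,
``[detection]`` and the optional ``[optics]``.  Unknown sections or keys are
rejected with the offending name so silent typos cannot alter the physics.
The bundled ``table1.toml`` reproduces the modelled instrument verbatim and
is the default everywhere.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .beams import GaussianBeamSpec, MediumSpec, PumpDriveSpec
from .nanolens import DetectionGeometry, ThermalLensScene
from .vectorial_psf import ObjectiveSpec

__all__ = ["RunConfig", "load_config", "table1_path"]

_SCHEMA: dict[str, dict[str, bool]] = {
    # section -> key -> required
    "probe_beam": {"wavelength_um": True, "waist_um": True, "medium_index": False},
    "pump_beam": {
        "wavelength_um": False,
        "wavenumber_cm1": False,
        "waist_um": True,
        "medium_index": False,
    },
    "pump_drive": {
        "average_power_mW": True,
        "duty_cycle": True,
        "modulation_frequency_kHz": True,
    },
    "medium": {
        "thermal_conductivity": True,
        "specific_heat_capacity": True,
        "density": True,
        "refractive_index": True,
        "thermo_optic_coefficient": True,
    },
    "absorber": {"cross_section_um2": True, "radius_um": True},
    "detection": {
        "theta_min_deg": True,
        "theta_max_deg": False,
        "numerical_aperture": False,
    },
    "optics": {
        "raman_na": False,
        "optir_na": False,
        "optir_collection_theta_min_deg": False,
        "apodization": False,
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Validated instrument parameters, assembled into domain objects."""

    probe: GaussianBeamSpec
    pump: GaussianBeamSpec
    drive: PumpDriveSpec
    medium: MediumSpec
    scene: ThermalLensScene
    detection: DetectionGeometry
    raman_objective: ObjectiveSpec
    optir_illumination: ObjectiveSpec
    optir_collection: ObjectiveSpec
    source_path: str = ""
    raw: dict = field(default_factory=dict, compare=False)


def table1_path() -> Path:
    """Path of the bundled instrument-table configuration."""
    return Path(str(resources.files("thermopsf").joinpath("data/table1.toml")))


def _validate_schema(doc: dict, path: str) -> None:
    for section in doc:
        if section not in _SCHEMA:
            raise ValueError(f"{path}: unknown section [{section}]")
        if not isinstance(doc[section], dict):
            raise ValueError(f"{path}: [{section}] must be a table")
        for key in doc[section]:
            if key not in _SCHEMA[section]:
                raise ValueError(f"{path}: unknown key {key!r} in section [{section}]")
    for section, keys in _SCHEMA.items():
        required = [k for k, req in keys.items() if req]
        if not required:
            continue
        if section not in doc:
            raise ValueError(f"{path}: missing required section [{section}]")
        for key in required:
            if key not in doc[section]:
                raise ValueError(f"{path}: missing key {key!r} in section [{section}]")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a TOML configuration (default: bundled table).

    Wavenumber input for the pump (``wavenumber_cm1``) is converted to a
    wavelength via λ[μm] = 10⁴/ν̃[cm⁻¹]; when both are present the explicit
    wavelength wins but the pair must agree within 0.5 %.  ``theta_max_deg``
    may be given directly or derived from a numerical aperture via
    θ_max = arcsin(NA/n0); when both are given they must agree within 0.1°.
    """
    p = Path(path) if path is not None else table1_path()
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    try:
        doc = tomllib.loads(p.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ValueError(f"{p}: invalid TOML: {exc}") from exc
    _validate_schema(doc, str(p))

    probe_sec = doc["probe_beam"]
    medium_sec = doc["medium"]
    n0 = float(medium_sec["refractive_index"])
    probe = GaussianBeamSpec(
        wavelength_um=float(probe_sec["wavelength_um"]),
        waist_um=float(probe_sec["waist_um"]),
        medium_index=float(probe_sec.get("medium_index", n0)),
    )

    pump_sec = doc["pump_beam"]
    lam = pump_sec.get("wavelength_um")
    nu = pump_sec.get("wavenumber_cm1")
    if lam is None and nu is None:
        raise ValueError(f"{p}: [pump_beam] needs wavelength_um or wavenumber_cm1")
    if nu is not None:
        lam_from_nu = 1.0e4 / float(nu)
        if lam is None:
            lam = lam_from_nu
        elif abs(lam_from_nu - float(lam)) / float(lam) > 5e-3:
            raise ValueError(
                f"{p}: [pump_beam] wavelength_um={lam} and wavenumber_cm1={nu} "
                f"(-> {lam_from_nu:.4f} um) disagree by more than 0.5%"
            )
    pump = GaussianBeamSpec(
        wavelength_um=float(lam),
        waist_um=float(pump_sec["waist_um"]),
        medium_index=float(pump_sec.get("medium_index", n0)),
    )

    drive_sec = doc["pump_drive"]
    drive = PumpDriveSpec(
        average_power_W=float(drive_sec["average_power_mW"]) * 1e-3,
        duty_cycle=float(drive_sec["duty_cycle"]),
        modulation_frequency_Hz=float(drive_sec["modulation_frequency_kHz"]) * 1e3,
    )

    medium = MediumSpec(
        thermal_conductivity=float(medium_sec["thermal_conductivity"]),
        specific_heat_capacity=float(medium_sec["specific_heat_capacity"]),
        density=float(medium_sec["density"]),
        refractive_index=n0,
        thermo_optic_coefficient=float(medium_sec["thermo_optic_coefficient"]),
    )

    det_sec = doc["detection"]
    tmin = float(det_sec["theta_min_deg"])
    tmax = det_sec.get("theta_max_deg")
    na = det_sec.get("numerical_aperture")
    if tmax is None and na is None:
        raise ValueError(f"{p}: [detection] needs theta_max_deg or numerical_aperture")
    if na is not None:
        tmax_from_na = math.degrees(math.asin(float(na) / n0))
        if tmax is None:
            tmax = tmax_from_na
        elif abs(float(tmax) - tmax_from_na) > 0.1:
            raise ValueError(
                f"{p}: [detection] theta_max_deg={tmax} and numerical_aperture={na} "
                f"(-> {tmax_from_na:.3f} deg) disagree by more than 0.1 deg"
            )
    detection = DetectionGeometry(theta_min_deg=tmin, theta_max_deg=float(tmax))

    abs_sec = doc["absorber"]
    scene = ThermalLensScene(
        cross_section_um2=float(abs_sec["cross_section_um2"]),
        bead_radius_um=float(abs_sec["radius_um"]),
        medium=medium,
        pump=pump,
        drive=drive,
        probe=probe,
    )

    optics = doc.get("optics", {})
    apod = optics.get("apodization", "uniform")
    raman_na = float(optics.get("raman_na", 0.55))
    optir_na = float(optics.get("optir_na", 0.5))
    col_tmin = float(optics.get("optir_collection_theta_min_deg", 0.0))
    raman_objective = ObjectiveSpec(raman_na, 0.0, n0, apod)
    optir_illumination = ObjectiveSpec(optir_na, 0.0, n0, apod)
    optir_collection = ObjectiveSpec(optir_na, col_tmin, n0, apod)

    return RunConfig(
        probe=probe,
        pump=pump,
        drive=drive,
        medium=medium,
        scene=scene,
        detection=detection,
        raman_objective=raman_objective,
        optir_illumination=optir_illumination,
        optir_collection=optir_collection,
        source_path=str(p),
        raw=doc,
    )
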