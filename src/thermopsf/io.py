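"""File I/O: CSV line profiles, TIFF/CSV scan images with pitch sidecars.

Profiles are two-column CSV (``coordinate_um,intensity``).  Images travel as
single-page grayscale TIFF (or a bare CSV grid) accompanied by a TOML
sidecar ``<image>.pitch.toml`` recording the pixel pitches and axis labels —
image formats do not carry physical scan coordinates.  Round trips preserve
values to float precision.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fitting import NanolensFitResult
from .profiles import LineProfile, ScanImage

__all__ = [
    "read_profile",
    "write_profile",
    "read_image",
    "write_image",
    "write_fit_report",
    "sidecar_path",
]


def read_profile(path: str | Path) -> LineProfile:
    """Read a two-column CSV profile; malformed cells are reported by row."""
    p = Path(path)
    try:
        df = pd.read_csv(p, comment="#")
    except Exception as exc:
        raise ValueError(f"{p}: cannot parse CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{p}: expected two columns (coordinate_um, intensity)")
    df = df.iloc[:, :2]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in numeric.index[bad][:5]]  # 1-based + header
        raise ValueError(f"{p}: non-numeric cell(s) at line(s) {rows}")
    return LineProfile(
        numeric.iloc[:, 0].to_numpy(), numeric.iloc[:, 1].to_numpy(),
        metadata={"source": str(p)},
    )


def write_profile(profile: LineProfile, path: str | Path) -> None:
    p = Path(path)
    pd.DataFrame(
        {"coordinate_um": profile.coordinate_um, "intensity": profile.intensity}
    ).to_csv(p, index=False, float_format="%.12g")


def sidecar_path(image_path: str | Path) -> Path:
    p = Path(image_path)
    return p.with_name(p.name + ".pitch.toml")


def write_image(image: ScanImage, path: str | Path) -> None:
    """Write TIFF (by suffix) or CSV grid, plus the pitch sidecar."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, image.pixel_values.astype(np.float32))
    else:
        np.savetxt(p, image.pixel_values, delimiter=",", fmt="%.9g")
    sidecar = sidecar_path(p)
    sidecar.write_text(
        "# pixel pitches of the accompanying scan image\n"
        f'pixel_pitch_fast_um = {image.pixel_pitch_fast_um!r}\n'
        f'pixel_pitch_slow_um = {image.pixel_pitch_slow_um!r}\n'
        f'axes_labels = ["{image.axes_labels[0]}", "{image.axes_labels[1]}"]\n'
    )


def read_image(path: str | Path) -> ScanImage:
    """Read TIFF or CSV grid; the pitch sidecar is mandatory."""
    p = Path(path)
    sidecar = sidecar_path(p)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"{p}: missing sidecar {sidecar.name}; write a TOML file next to the "
            "image with keys pixel_pitch_fast_um, pixel_pitch_slow_um and "
            'optional axes_labels = ["x", "z"]'
        )
    meta = tomllib.loads(sidecar.read_text())
    for key in ("pixel_pitch_fast_um", "pixel_pitch_slow_um"):
        if key not in meta:
            raise ValueError(f"{sidecar}: missing key {key!r}")
    if p.suffix.lower() in (".tif", ".tiff"):
        values = np.asarray(tifffile.imread(p), dtype=float)
    else:
        values = np.loadtxt(p, delimiter=",", dtype=float)
    labels = tuple(meta.get("axes_labels", ("x", "z")))
    return ScanImage(
        values,
        float(meta["pixel_pitch_fast_um"]),
        float(meta["pixel_pitch_slow_um"]),
        (str(labels[0]), str(labels[1])),
        metadata={"source": str(p)},
    )


def write_fit_report(result: NanolensFitResult, path: str | Path, settings: dict | None = None) -> None:
    """JSON fit report: estimates, 1-sd errors, residual, settings snapshot."""
    payload = {
        "focus_offset_um": result.focus_offset_um,
        "focus_offset_sd_um": result.focus_offset_sd_um,
        "cross_section_m2": result.cross_section_m2,
        "cross_section_sd_m2": result.cross_section_sd_m2,
        "residual_norm": result.residual_norm,
        "n_evaluations": result.n_evaluations,
        "converged": result.converged,
        "settings": settings or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
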