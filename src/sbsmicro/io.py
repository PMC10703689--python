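"""File formats: spectrum CSV, spectral-cube HDF5, parameter-map TIFF.

Conventions: frequencies are serialized in GHz, lengths in µm, times in
ms, and field names carry their units.  Masked pixels are NaN in TIFF
maps and an explicit boolean ``/mask`` dataset in HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .physics import InvalidParameterError
from .synth import FrequencyAxis, ScanGeometry, Spectrum
from .reconstruct import BrillouinMaps, SpectralCube

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_cube_h5",
    "write_cube_h5",
    "write_maps_tiff",
    "read_map_tiff",
]

_GEOMETRY_ATTRS = [
    "nx", "ny", "nz",
    "step_x_um", "step_y_um", "step_z_um",
    "pixel_time_ms", "n_freq", "fast_axis",
    "serpentine", "z_flip", "stage_delay_ms",
]


# ---------------------------------------------------------------------------
# spectrum CSV
# ---------------------------------------------------------------------------

def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column CSV (frequency_ghz, gain) with `# key: value` metadata."""
    path = Path(path)
    lines = [
        f"# integration_time_ms: {spectrum.integration_time_ms!r}",
        f"# dc_level: {spectrum.dc_level!r}",
        f"# seed: {spectrum.seed!r}",
        "frequency_ghz,gain",
    ]
    for f, v in zip(spectrum.axis.values, spectrum.values):
        lines.append(f"{float(f)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    path = Path(path)
    meta: dict[str, str] = {}
    freqs: list[float] = []
    vals: list[float] = []
    header_seen = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols != ["frequency_ghz", "gain"]:
                raise InvalidParameterError(
                    f"{path}: expected columns frequency_ghz,gain; got {cols}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise InvalidParameterError(f"{path}: malformed row {line!r}")
        freqs.append(float(parts[0]))
        vals.append(float(parts[1]))
    if not header_seen or not freqs:
        raise InvalidParameterError(f"{path}: no spectrum data found")
    axis = FrequencyAxis.from_values(np.array(freqs))  # validates monotone/uniform
    seed_str = meta.get("seed", "None")
    return Spectrum(
        axis=axis,
        values=np.array(vals),
        integration_time_ms=float(meta.get("integration_time_ms", 20.0)),
        dc_level=float(meta.get("dc_level", 100.0)),
        seed=None if seed_str == "None" else int(seed_str),
    )


# ---------------------------------------------------------------------------
# spectral-cube HDF5
# ---------------------------------------------------------------------------

def write_cube_h5(
    cube: SpectralCube,
    path: str | Path,
    ground_truth: np.ndarray | None = None,
) -> None:
    """HDF5 layout: /axis, /data [n_freq × n_pixels], /mask, /geometry attrs,
    optional /ground_truth (ignored by fitting)."""
    g = cube.geometry
    with h5py.File(path, "w") as h5:
        if cube.axis is not None:
            h5.create_dataset("axis", data=cube.axis.values)
        h5.create_dataset(
            "data", data=cube.data.reshape(g.n_freq, g.n_pixels, order="F")
        )
        h5.create_dataset("mask", data=cube.mask.reshape(g.n_pixels, order="F"))
        geo = h5.create_group("geometry")
        for name in _GEOMETRY_ATTRS:
            geo.attrs[name] = getattr(g, name)
        if ground_truth is not None:
            h5.create_dataset("ground_truth", data=ground_truth)


def read_cube_h5(path: str | Path) -> SpectralCube:
    with h5py.File(path, "r") as h5:
        if "geometry" not in h5:
            raise InvalidParameterError(f"{path}: missing /geometry group")
        attrs = dict(h5["geometry"].attrs)
        for name in _GEOMETRY_ATTRS:
            if name not in attrs:
                raise InvalidParameterError(
                    f"{path}: geometry attribute {name!r} is missing"
                )
        geometry = ScanGeometry(
            nx=int(attrs["nx"]),
            ny=int(attrs["ny"]),
            nz=int(attrs["nz"]),
            step_x_um=float(attrs["step_x_um"]),
            step_y_um=float(attrs["step_y_um"]),
            step_z_um=float(attrs["step_z_um"]),
            pixel_time_ms=float(attrs["pixel_time_ms"]),
            n_freq=int(attrs["n_freq"]),
            fast_axis=str(attrs["fast_axis"]),
            serpentine=bool(attrs["serpentine"]),
            z_flip=bool(attrs["z_flip"]),
            stage_delay_ms=float(attrs["stage_delay_ms"]),
        )
        data = np.asarray(h5["data"])
        if data.shape != (geometry.n_freq, geometry.n_pixels):
            raise InvalidParameterError(
                f"{path}: /data shape {data.shape} inconsistent with geometry"
            )
        cube = data.reshape(
            geometry.n_freq, geometry.nx, geometry.ny, geometry.nz, order="F"
        )
        mask = (
            np.asarray(h5["mask"]).reshape(
                geometry.nx, geometry.ny, geometry.nz, order="F"
            )
            if "mask" in h5
            else None
        )
        axis = (
            FrequencyAxis.from_values(np.asarray(h5["axis"]))
            if "axis" in h5
            else None
        )
    return SpectralCube(data=cube, geometry=geometry, axis=axis, mask=mask)


# ---------------------------------------------------------------------------
# parameter-map TIFF + sidecar
# ---------------------------------------------------------------------------

def write_maps_tiff(maps: BrillouinMaps, out_dir: str | Path) -> dict[str, Path]:
    """One 32-bit float TIFF per quantity plus a JSON sidecar.

    Images are written as (z, y, x) stacks; masked pixels carry NaN.
    Returns the mapping quantity → written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = maps.geometry
    written: dict[str, Path] = {}
    for name, img in maps.as_dict().items():
        arr = np.where(maps.mask, img, np.nan).T.astype(np.float32)  # (nz, ny, nx)
        path = out_dir / f"{name}.tiff"
        tifffile.imwrite(path, arr, photometric="minisblack")
        written[name] = path
    sidecar = {
        "units": {
            "shift_ghz": "GHz",
            "linewidth_ghz": "GHz",
            "amplitude": "detector units",
            "gain": "dimensionless",
            "snr": "dimensionless",
            "n_peaks": "count",
            "metric": "fraction",
        },
        "axis_order": "zyx",
        "pixel_steps_um": {"x": g.step_x_um, "y": g.step_y_um, "z": g.step_z_um},
        "shape_xyz": [g.nx, g.ny, g.nz],
        "masked_pixel_sentinel": "NaN",
    }
    sidecar_path = out_dir / "maps.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    written["sidecar"] = sidecar_path
    return written


def read_map_tiff(path: str | Path) -> np.ndarray:
    """Read a map written by :func:`write_maps_tiff` back to (nx, ny, nz)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:  # single-plane stacks collapse on disk
        arr = arr[None, ...]
    return np.asarray(arr).T.astype(float)
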