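"""Raster-scan reconstruction: stream → spectral cube → Brillouin maps.

The instrument emits one long 1-D sample array, frequency fastest.  The
array is reshaped into a [frequency; pixels] matrix, pixels are folded
back onto the scan grid undoing the serpentine (bidirectional) fast axis,
every second line is displaced by round(stage_delay / pixel_time) pixels
to compensate the stage lag, and every other z-plane is flipped (z-scan
pattern).  Reconstruction is a pure permutation plus masking: no sample
value is ever interpolated or fabricated, and pixels vacated by the line
shift are masked.

Per-pixel fit results are then assembled into maps of shift, linewidth,
amplitude, gain and SNR; a multi-peak pixel contributes its
highest-amplitude peak to the scalar maps while all peaks remain in the
per-pixel table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .physics import InvalidParameterError
from .synth import FrequencyAxis, ScanGeometry, Spectrum
from .fitting import FitResult

__all__ = [
    "SpectralCube",
    "BrillouinMaps",
    "reshape_stream",
    "fold_serpentine",
    "correct_line_shift",
    "flip_alternate_planes",
    "reconstruct_stream",
    "fit_cube",
    "build_maps",
]


@dataclass
class SpectralCube:
    """Per-pixel spectra on the scan grid, shape [n_freq, nx, ny, nz]."""

    data: np.ndarray
    geometry: ScanGeometry
    axis: FrequencyAxis | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        g = self.geometry
        expected = (g.n_freq, g.nx, g.ny, g.nz)
        if self.data.shape != expected:
            raise InvalidParameterError(
                f"cube shape {self.data.shape} != expected {expected}"
            )
        if self.mask is None:
            self.mask = np.ones((g.nx, g.ny, g.nz), dtype=bool)
        elif self.mask.shape != expected[1:]:
            raise InvalidParameterError("mask shape does not match the grid")

    @property
    def n_pixels(self) -> int:
        return self.geometry.n_pixels

    def spectrum_at(self, ix: int, iy: int, iz: int, **kwargs) -> Spectrum:
        if self.axis is None:
            raise InvalidParameterError("cube carries no frequency axis")
        return Spectrum(axis=self.axis, values=self.data[:, ix, iy, iz], **kwargs)


@dataclass
class BrillouinMaps:
    """Per-pixel parameter images plus the validity mask and full peak table."""

    shift_ghz: np.ndarray
    linewidth_ghz: np.ndarray
    amplitude: np.ndarray
    gain: np.ndarray
    snr: np.ndarray
    n_peaks: np.ndarray
    metric: np.ndarray
    mask: np.ndarray
    geometry: ScanGeometry
    table: pd.DataFrame | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "shift_ghz": self.shift_ghz,
            "linewidth_ghz": self.linewidth_ghz,
            "amplitude": self.amplitude,
            "gain": self.gain,
            "snr": self.snr,
            "n_peaks": self.n_peaks,
            "metric": self.metric,
        }


# ---------------------------------------------------------------------------
# stream -> cube
# ---------------------------------------------------------------------------

def reshape_stream(stream: np.ndarray, n_freq: int) -> np.ndarray:
    """Reshape the 1-D stream into [frequency; pixels]; column p holds
    samples p·n_freq … (p+1)·n_freq − 1."""
    stream = np.asarray(stream)
    if n_freq < 1:
        raise InvalidParameterError("n_freq must be >= 1")
    if stream.ndim != 1:
        raise InvalidParameterError("stream must be one-dimensional")
    rem = stream.size % n_freq
    if rem != 0:
        raise InvalidParameterError(
            f"stream length {stream.size} is not divisible by n_freq={n_freq} "
            f"(remainder {rem})"
        )
    return stream.reshape(-1, n_freq).T


def fold_serpentine(matrix: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Fold [n_freq, n_pixels] into [n_freq, nx, rows, nz] in acquisition
    line order, reversing odd serpentine lines back to +x."""
    g = geometry
    if matrix.shape != (g.n_freq, g.n_pixels):
        raise InvalidParameterError(
            f"matrix shape {matrix.shape} != ({g.n_freq}, {g.n_pixels})"
        )
    cube = matrix.reshape(g.n_freq, g.nz, g.ny, g.nx).transpose(0, 3, 2, 1).copy()
    if g.serpentine:
        cube[:, :, 1::2, :] = cube[:, ::-1, 1::2, :].copy()
    return cube


def correct_line_shift(
    grid: np.ndarray,
    stage_delay_ms: float,
    pixel_time_ms: float,
    direction: int = 1,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Displace every second fast-axis line by round(delay/pixel_time) px.

    ``grid`` has x on axis −3 and line index on axis −2 (an [..., nx, ny,
    nz] pixel grid or a [n_freq, nx, ny, nz] cube).  Returns the corrected
    grid and the validity mask; vacated pixels are masked, never wrapped.
    """
    if stage_delay_ms < 0:
        raise InvalidParameterError("stage_delay_ms must be >= 0")
    if not pixel_time_ms > 0:
        raise InvalidParameterError("pixel_time_ms must be > 0")
    if direction not in (1, -1):
        raise InvalidParameterError("direction must be +1 or -1")
    nx = grid.shape[-3]
    s = int(round(stage_delay_ms / pixel_time_ms))
    if mask is None:
        mask = np.ones(grid.shape[-3:], dtype=bool)
    if s == 0:
        return grid.copy(), mask.copy()
    if s >= nx:
        raise InvalidParameterError(
            f"line shift of {s} px is not smaller than the line length {nx}"
        )
    out = grid.astype(float, copy=True)
    out_mask = mask.copy()
    if direction == 1:
        out[..., s:, 1::2, :] = grid[..., : nx - s, 1::2, :]
        out_mask[s:, 1::2, :] = mask[: nx - s, 1::2, :]
        out[..., :s, 1::2, :] = np.nan
        out_mask[:s, 1::2, :] = False
    else:
        out[..., : nx - s, 1::2, :] = grid[..., s:, 1::2, :]
        out_mask[: nx - s, 1::2, :] = mask[s:, 1::2, :]
        out[..., nx - s :, 1::2, :] = np.nan
        out_mask[nx - s :, 1::2, :] = False
    return out, out_mask


def flip_alternate_planes(stack: np.ndarray) -> np.ndarray:
    """Reverse odd-indexed z-planes along the line (slow) axis.

    Involution: applying twice restores the input.  ``stack`` has the line
    axis at −2 and z at −1.
    """
    out = stack.copy()
    out[..., 1::2] = out[..., ::-1, 1::2].copy()
    return out


def reconstruct_stream(
    stream: np.ndarray,
    geometry: ScanGeometry,
    axis: FrequencyAxis | None = None,
) -> SpectralCube:
    """Full stream → cube pipeline: reshape, unfold serpentine, undo the
    stage-delay line shift, flip alternate z-planes."""
    matrix = reshape_stream(stream, geometry.n_freq)
    if matrix.shape[1] != geometry.n_pixels:
        raise InvalidParameterError(
            f"stream holds {matrix.shape[1]} pixels; geometry expects "
            f"{geometry.n_pixels}"
        )
    cube = fold_serpentine(matrix, geometry)
    mask = np.ones(cube.shape[1:], dtype=bool)
    if geometry.line_shift_px > 0:
        # with a serpentine fast axis the stage lag appears as a -x
        # displacement in grid coordinates, so the correction shifts +x
        direction = 1 if geometry.serpentine else -1
        cube, mask = correct_line_shift(
            cube,
            geometry.stage_delay_ms,
            geometry.pixel_time_ms,
            direction=direction,
            mask=mask,
        )
    if geometry.z_flip and geometry.nz > 1:
        cube = flip_alternate_planes(cube)
        mask = flip_alternate_planes(mask)
    return SpectralCube(data=cube, geometry=geometry, axis=axis, mask=mask)


# ---------------------------------------------------------------------------
# cube -> maps
# ---------------------------------------------------------------------------

def fit_cube(
    cube: SpectralCube,
    fitter: Callable[[Spectrum], FitResult],
    dc_level: float = 100.0,
) -> list[FitResult | None]:
    """Fit every unmasked pixel; masked pixels yield None.

    Results are returned flat in grid raster order (x fastest, then y,
    then z) for consumption by :func:`build_maps`.
    """
    g = cube.geometry
    out: list[FitResult | None] = []
    for iz in range(g.nz):
        for iy in range(g.ny):
            for ix in range(g.nx):
                if not cube.mask[ix, iy, iz]:
                    out.append(None)
                    continue
                spec = cube.spectrum_at(ix, iy, iz, dc_level=dc_level)
                out.append(fitter(spec))
    # reorder from z,y,x loop order (x fastest) - already x fastest
    return out


def build_maps(
    fits: Sequence[FitResult | None],
    geometry: ScanGeometry,
    dc_level: float = 100.0,
    snr: Sequence[float] | None = None,
    metric: Sequence[float] | None = None,
) -> BrillouinMaps:
    """Assemble per-pixel fits into parameter maps in phantom coordinates.

    ``fits`` is flat in grid raster order, x fastest.  Pixels that are None
    or non-converged are masked (NaN in every map).  Multi-peak pixels
    report their highest-amplitude peak in the scalar maps; every peak of
    every pixel is kept in the ``table`` attribute.
    """
    g = geometry
    n = g.n_pixels
    if len(fits) != n:
        raise InvalidParameterError(f"{len(fits)} fits for {n} pixels")
    shape = (g.nx, g.ny, g.nz)
    flat = {
        k: np.full(n, np.nan)
        for k in ("shift", "linewidth", "amplitude", "gain", "snr", "npeaks", "metric")
    }
    mask = np.zeros(n, dtype=bool)
    rows = []
    for i, fit in enumerate(fits):
        ix = i % g.nx
        iy = (i // g.nx) % g.ny
        iz = i // (g.nx * g.ny)
        if fit is None or not fit.converged:
            continue
        mask[i] = True
        top = fit.dominant
        flat["shift"][i] = top.shift_ghz
        flat["linewidth"][i] = top.fwhm_ghz
        flat["amplitude"][i] = top.amplitude
        flat["gain"][i] = top.amplitude / dc_level
        flat["npeaks"][i] = fit.n_peaks
        if snr is not None:
            flat["snr"][i] = snr[i]
        if metric is not None:
            flat["metric"][i] = metric[i]
        for k, p in enumerate(fit.peaks):
            rows.append(
                {
                    "ix": ix,
                    "iy": iy,
                    "iz": iz,
                    "peak": k,
                    "shift_ghz": p.shift_ghz,
                    "fwhm_ghz": p.fwhm_ghz,
                    "amplitude": p.amplitude,
                    "gain": p.amplitude / dc_level,
                    "baseline": fit.baseline,
                    "residual_rms": fit.residual_rms,
                }
            )
    def to_img(v: np.ndarray) -> np.ndarray:
        return v.reshape(shape, order="F")

    table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=[
            "ix", "iy", "iz", "peak", "shift_ghz", "fwhm_ghz",
            "amplitude", "gain", "baseline", "residual_rms",
        ]
    )
    return BrillouinMaps(
        shift_ghz=to_img(flat["shift"]),
        linewidth_ghz=to_img(flat["linewidth"]),
        amplitude=to_img(flat["amplitude"]),
        gain=to_img(flat["gain"]),
        snr=to_img(flat["snr"]),
        n_peaks=to_img(flat["npeaks"]),
        metric=to_img(flat["metric"]),
        mask=mask.reshape(shape, order="F"),
        geometry=geometry,
        table=table,
    )
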