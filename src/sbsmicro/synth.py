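"""Synthetic SBG data: noisy spectra, repeat series, phantoms and scan streams.

Everything the analysis pipeline consumes can be generated here with known
ground truth.  The noise model is additive, homoscedastic Gaussian noise
referenced to the tallest peak (SNR = peak amplitude / σ), matching how the
instrument's SNR is defined from the off-resonance standard deviation; noise
scales with integration time t as σ ∝ t^(−1/2) (shot-noise limit).

Default "water" conditions: single Lorentzian at 5.00 GHz with 0.459 GHz
FWHM on a 100-point 4–6 GHz axis, 20 ms integration, SNR 38 — the
operating point of the instrument this package models.

All generators take explicit integer seeds and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .physics import GainModel, InvalidParameterError, LorentzianPeak, sbg_spectrum

__all__ = [
    "FrequencyAxis",
    "Spectrum",
    "SpectrumGroup",
    "PhantomSpec",
    "ScanGeometry",
    "WATER_PEAK",
    "DEFAULT_AXIS",
    "DEFAULT_SNR",
    "DEFAULT_INTEGRATION_MS",
    "make_spectrum",
    "make_spectrum_series",
    "make_phantom",
    "make_scan_stream",
]


@dataclass(frozen=True)
class FrequencyAxis:
    """Uniform, strictly increasing pump–probe detuning axis in GHz."""

    start_ghz: float
    end_ghz: float
    n_points: int = 100

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InvalidParameterError("n_points must be >= 3")
        if not self.end_ghz > self.start_ghz:
            raise InvalidParameterError("end_ghz must exceed start_ghz")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start_ghz, self.end_ghz, self.n_points)

    @property
    def step_ghz(self) -> float:
        return (self.end_ghz - self.start_ghz) / (self.n_points - 1)

    @property
    def span_ghz(self) -> float:
        return self.end_ghz - self.start_ghz

    @classmethod
    def from_values(cls, values: np.ndarray) -> "FrequencyAxis":
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size < 3:
            raise InvalidParameterError("axis needs >= 3 one-dimensional values")
        d = np.diff(v)
        if not np.all(d > 0):
            raise InvalidParameterError("axis values must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
            raise InvalidParameterError("axis spacing must be uniform")
        return cls(float(v[0]), float(v[-1]), int(v.size))

    def shifted(self, delta_ghz: float) -> "FrequencyAxis":
        return FrequencyAxis(
            self.start_ghz + delta_ghz, self.end_ghz + delta_ghz, self.n_points
        )


#: water resonance used throughout the tests and defaults
WATER_PEAK = LorentzianPeak(shift_ghz=5.00, fwhm_ghz=0.459, amplitude=1.0)
DEFAULT_AXIS = FrequencyAxis(4.0, 6.0, 100)
DEFAULT_SNR = 38.0
DEFAULT_INTEGRATION_MS = 20.0


@dataclass
class Spectrum:
    """One acquired (or simulated) gain spectrum.

    `dc_level` is the DC photodetector component the Brillouin gain is
    normalised by; `seed` records the noise seed when simulated.
    """

    axis: FrequencyAxis
    values: np.ndarray
    integration_time_ms: float = DEFAULT_INTEGRATION_MS
    dc_level: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.axis.n_points,):
            raise InvalidParameterError(
                f"values length {self.values.shape} does not match axis "
                f"({self.axis.n_points} points)"
            )
        if not self.dc_level > 0:
            raise InvalidParameterError("dc_level must be > 0")


@dataclass
class SpectrumGroup:
    """Repeated acquisitions at one integration time."""

    integration_time_ms: float
    spectra: list[Spectrum]


def make_spectrum(
    axis: FrequencyAxis,
    peaks: Sequence[LorentzianPeak],
    snr: float = DEFAULT_SNR,
    dc_level: float = 100.0,
    integration_time_ms: float = DEFAULT_INTEGRATION_MS,
    seed: int | None = 0,
    model: GainModel | None = None,
) -> Spectrum:
    """Simulate one spectrum: noiseless Lorentzian sum + Gaussian noise.

    The noise standard deviation is (max peak amplitude)/snr; ``snr=np.inf``
    returns the noiseless model exactly.
    """
    if not snr > 0:
        raise InvalidParameterError(f"snr must be > 0, got {snr}")
    clean = sbg_spectrum(axis.values, peaks, model=model)
    if np.isinf(snr):
        values = clean
    else:
        amp = max((p.amplitude for p in peaks), default=0.0)
        sigma = amp / snr
        rng = np.random.default_rng(seed)
        values = clean + rng.normal(0.0, sigma, size=axis.n_points)
    return Spectrum(
        axis=axis,
        values=values,
        integration_time_ms=integration_time_ms,
        dc_level=dc_level,
        seed=seed,
    )


def make_spectrum_series(
    axis: FrequencyAxis,
    peak: LorentzianPeak,
    n_repeats: int,
    integration_times_ms: Sequence[float],
    base_snr: float = DEFAULT_SNR,
    base_time_ms: float = DEFAULT_INTEGRATION_MS,
    seed: int = 0,
) -> list[SpectrumGroup]:
    """Repeated single-peak acquisitions across integration times.

    The SNR is specified at a reference time and rescaled as
    snr(t) = base_snr * sqrt(t / base_time), i.e. σ ∝ t^(−1/2) — the
    shot-noise-limited scaling the precision-versus-time study measures.
    """
    if n_repeats < 2:
        raise InvalidParameterError("n_repeats must be >= 2")
    times = [float(t) for t in integration_times_ms]
    if any(t <= 0 for t in times):
        raise InvalidParameterError("integration times must be > 0")
    rng = np.random.default_rng(seed)
    groups: list[SpectrumGroup] = []
    for t in times:
        snr_t = base_snr * np.sqrt(t / base_time_ms)
        child_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
        spectra = [
            make_spectrum(
                axis, [peak], snr=snr_t, integration_time_ms=t, seed=int(s)
            )
            for s in child_seeds
        ]
        groups.append(SpectrumGroup(integration_time_ms=t, spectra=spectra))
    return groups


# ---------------------------------------------------------------------------
# phantoms and raster streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanGeometry:
    """Raster-scan layout: grid, stepping, timing and traversal pattern.

    ``serpentine`` means odd-numbered fast-axis lines are scanned in the
    reverse direction; ``z_flip`` means odd z-planes traverse their lines in
    reversed slow-axis order; ``stage_delay_ms`` is the stage lag that
    displaces every second line's recorded content.
    """

    nx: int
    ny: int
    nz: int = 1
    step_x_um: float = 0.25
    step_y_um: float = 0.25
    step_z_um: float = 1.0
    pixel_time_ms: float = DEFAULT_INTEGRATION_MS
    n_freq: int = 100
    fast_axis: str = "x"
    serpentine: bool = True
    z_flip: bool = True
    stage_delay_ms: float = 0.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise InvalidParameterError("grid dimensions must be >= 1")
        if not self.pixel_time_ms > 0:
            raise InvalidParameterError("pixel_time_ms must be > 0")
        if self.stage_delay_ms < 0:
            raise InvalidParameterError("stage_delay_ms must be >= 0")
        if self.fast_axis != "x":
            raise InvalidParameterError("only fast_axis='x' is supported")

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def line_shift_px(self) -> int:
        """Per-line displacement in pixels, round(stage_delay / pixel_time)."""
        return int(round(self.stage_delay_ms / self.pixel_time_ms))


@dataclass
class PhantomSpec:
    """Ground-truth material layout for a synthetic scan.

    ``labels`` holds a material name per pixel on an (nx, ny, nz) grid;
    ``materials`` maps each name to its Brillouin peaks (an empty list means
    no resonance inside the scanned band, e.g. cover glass).
    """

    labels: np.ndarray
    materials: Mapping[str, list[LorentzianPeak]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidParameterError("labels must be an (nx, ny, nz) array")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.materials)
        if missing:
            raise InvalidParameterError(f"labels missing from material table: {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def peaks_at(self, ix: int, iy: int, iz: int) -> list[LorentzianPeak]:
        return list(self.materials[str(self.labels[ix, iy, iz])])


# material resonances used by the standard phantoms (GHz)
_BEAD = LorentzianPeak(4.07, 0.459, 1.0)      # PDMS bead
_AGAROSE = LorentzianPeak(5.12, 0.459, 1.0)   # 1% agarose
_OIL = LorentzianPeak(7.04, 0.50, 1.0)        # immersion oil
_LAYER_A = LorentzianPeak(5.03, 0.46, 1.0)
_LAYER_B = LorentzianPeak(5.80, 0.46, 0.8)


def make_phantom(kind: str, geometry: ScanGeometry) -> PhantomSpec:
    """Build a ground-truth phantom on the scan grid.

    kinds
    -----
    ``water``
        uniform single water peak everywhere.
    ``bead_in_agarose``
        a 4.07 GHz disk (radius min(nx,ny)/4) embedded in 5.12 GHz agarose;
        the lateral-resolution phantom.
    ``oil_glass_edge``
        7.04 GHz oil in the lower half of z, cover glass (no in-band peak)
        above; the axial-resolution phantom.
    ``two_layer``
        5.03 GHz below / 5.80 GHz above a y-boundary, with a double-peak
        overlap stripe where both materials sit inside the focal volume.
    """
    nx, ny, nz = geometry.nx, geometry.ny, geometry.nz
    labels = np.empty((nx, ny, nz), dtype="U16")
    if kind == "water":
        labels[:] = "water"
        materials = {"water": [WATER_PEAK]}
    elif kind == "bead_in_agarose":
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        radius = min(nx, ny) / 4.0
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        disk = (ix - cx) ** 2 + (iy - cy) ** 2 <= radius**2
        labels[:] = "agarose"
        labels[disk, :] = "bead"
        materials = {"bead": [_BEAD], "agarose": [_AGAROSE]}
    elif kind == "oil_glass_edge":
        labels[:] = "glass"
        labels[:, :, : max(1, nz // 2)] = "oil"
        materials = {"oil": [_OIL], "glass": []}
    elif kind == "two_layer":
        half = max(1, ny // 8)  # overlap stripe half-width in pixels
        labels[:] = "layer_a"
        labels[:, ny // 2 + half :, :] = "layer_b"
        labels[:, ny // 2 - half : ny // 2 + half, :] = "overlap"
        materials = {
            "layer_a": [_LAYER_A],
            "layer_b": [_LAYER_B],
            "overlap": [_LAYER_A, _LAYER_B],
        }
    else:
        raise InvalidParameterError(f"unknown phantom kind {kind!r}")
    return PhantomSpec(labels=labels, materials=materials)


def ideal_cube(phantom: PhantomSpec, axis: FrequencyAxis) -> np.ndarray:
    """Noiseless per-pixel spectra, shape [n_freq, nx, ny, nz]."""
    nx, ny, nz = phantom.shape
    # evaluate each material once, then scatter
    spectra = {
        name: sbg_spectrum(axis.values, peaks) if peaks else np.zeros(axis.n_points)
        for name, peaks in phantom.materials.items()
    }
    cube = np.zeros((axis.n_points, nx, ny, nz))
    for name, spec in spectra.items():
        mask = phantom.labels == name
        cube[:, mask] = spec[:, None]
    return cube


def make_scan_stream(
    phantom: PhantomSpec,
    geometry: ScanGeometry,
    axis: FrequencyAxis,
    snr: float = np.inf,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Emulate raster acquisition of a phantom as a 1-D sample stream.

    Frequency is the fastest-varying index.  Pixels follow the serpentine
    fast axis, odd z-planes are traversed with the slow-axis line order
    reversed when ``z_flip`` is set, and when ``stage_delay_ms`` > 0 every
    second line's recorded content lags the commanded trajectory by
    round(delay / pixel_time) pixels (leading samples are blank).

    Returns ``(stream, truth)`` where ``truth`` is the noiseless ideal cube
    in phantom coordinates, shape [n_freq, nx, ny, nz].
    """
    if phantom.shape != (geometry.nx, geometry.ny, geometry.nz):
        raise InvalidParameterError(
            f"phantom shape {phantom.shape} does not match geometry "
            f"({geometry.nx}, {geometry.ny}, {geometry.nz})"
        )
    if axis.n_points != geometry.n_freq:
        raise InvalidParameterError(
            f"axis has {axis.n_points} points but geometry.n_freq is "
            f"{geometry.n_freq}"
        )
    if not snr > 0:
        raise InvalidParameterError("snr must be > 0")

    truth = ideal_cube(phantom, axis)
    nx, ny, nz = phantom.shape
    s = geometry.line_shift_px
    if s >= nx and s > 0:
        raise InvalidParameterError("line shift exceeds the line length")

    chunks: list[np.ndarray] = []
    for iz in range(nz):
        rows = range(ny)
        if geometry.z_flip and iz % 2 == 1:
            rows = reversed(rows)  # type: ignore[assignment]
        for acq_idx, iy in enumerate(rows):
            line = truth[:, :, iy, iz]  # [n_freq, nx] in +x order
            if geometry.serpentine and acq_idx % 2 == 1:
                line = line[:, ::-1]
            if s > 0 and acq_idx % 2 == 1:
                lagged = np.zeros_like(line)
                lagged[:, s:] = line[:, : nx - s]
                line = lagged
            chunks.append(line.T.ravel())  # pixel-major, frequency fastest
    stream = np.concatenate(chunks)

    if not np.isinf(snr):
        amp = max(
            (p.amplitude for peaks in phantom.materials.values() for p in peaks),
            default=0.0,
        )
        rng = np.random.default_rng(seed)
        stream = stream + rng.normal(0.0, amp / snr, size=stream.size)
    return stream, truth
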