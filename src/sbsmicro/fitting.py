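"""Detrending and (multi-)Lorentzian least-squares fitting of SBG spectra.

The acquisition stream is first high-pass filtered along acquisition time
(zero-phase, first-order Butterworth, 50 Hz default cutoff — roughly one
spectrum period) to remove the slowly drifting DC component of the lock-in
output.  Each per-pixel spectrum is then fit with a sum of one to three
Lorentzians plus a constant baseline by trust-region nonlinear least
squares.  The fitted parameters give the three Brillouin contrasts per
peak: shift Ω_B (center), linewidth Γ_B (FWHM) and gain
G_B = amplitude / DC level; the per-spectrum SNR is the fitted amplitude
over the off-resonance standard deviation.

Initialization is data driven: the center starts at the arg-max of a
smoothed copy of the spectrum, the FWHM at the half-maximum crossing
width, the amplitude at max-minus-baseline.  Multi-peak fits start at the
K most prominent smoothed local maxima; when fewer significant maxima
exist the dominant peak is split into overlapped components, which lets
the optimizer model shoulders without being seeded on noise wiggles.

Model-order choice between one and two peaks is deliberately *not* made
here; see :mod:`sbsmicro.classify` for the derivative-offset test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .physics import InvalidParameterError, LorentzianPeak
from .synth import Spectrum

__all__ = [
    "FitResult",
    "UnboundedSNRError",
    "NoiseWindowError",
    "detrend_highpass",
    "fit_lorentzian",
    "fit_multi_lorentzian",
    "brillouin_gain",
    "estimate_snr",
]


class UnboundedSNRError(ValueError):
    """The noise window has zero standard deviation (noiseless input)."""


class NoiseWindowError(ValueError):
    """The noise window overlaps a fitted peak or holds too few samples."""


@dataclass
class FitResult:
    """Outcome of a (multi-)Lorentzian fit.

    Peaks are sorted by ascending shift (ties broken by descending
    amplitude).  Standard errors come from the covariance of the
    least-squares estimate and are NaN when unavailable.
    """

    peaks: list[LorentzianPeak]
    baseline: float = 0.0
    shift_err_ghz: np.ndarray = field(default_factory=lambda: np.array([]))
    fwhm_err_ghz: np.ndarray = field(default_factory=lambda: np.array([]))
    amplitude_err: np.ndarray = field(default_factory=lambda: np.array([]))
    residual_rms: float = 0.0
    converged: bool = False
    degenerate: bool = False
    message: str = ""

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def dominant(self) -> LorentzianPeak:
        """Highest-amplitude peak (maps report this one for multi-peak pixels)."""
        return max(self.peaks, key=lambda p: p.amplitude)


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def detrend_highpass(
    stream: np.ndarray, sample_rate_hz: float, cutoff_hz: float = 50.0
) -> np.ndarray:
    """Zero-phase first-order Butterworth high-pass along acquisition time.

    Removes the DC and sub-cutoff drift of the concatenated acquisition
    stream without biasing peak positions (forward–backward filtering has
    zero phase delay).
    """
    stream = np.asarray(stream, dtype=float)
    if not cutoff_hz > 0:
        raise InvalidParameterError("cutoff_hz must be > 0")
    if cutoff_hz >= sample_rate_hz / 2.0:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate "
            f"{sample_rate_hz / 2:.6g} Hz"
        )
    sos = signal.butter(1, cutoff_hz, btype="highpass", fs=sample_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, stream)


# ---------------------------------------------------------------------------
# model and initialization helpers
# ---------------------------------------------------------------------------

def _model(f: np.ndarray, *params: float) -> np.ndarray:
    """Sum of Lorentzians plus constant baseline.

    params = (A1, c1, w1, ..., Ak, ck, wk, b) with w the FWHM.
    """
    out = np.full_like(f, params[-1])
    for i in range(0, len(params) - 1, 3):
        a, c, w = params[i : i + 3]
        u = (f - c) / (w / 2.0)
        out = out + a / (1.0 + u * u)
    return out


def _smooth(values: np.ndarray) -> np.ndarray:
    n = values.size
    window = min(11, n if n % 2 == 1 else n - 1)
    if window < 5:
        return values.copy()
    return signal.savgol_filter(values, window, polyorder=2)


def _robust_noise(values: np.ndarray) -> float:
    # std of first differences of white noise is sigma*sqrt(2);
    # MAD-based version is insensitive to the peak itself
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / (0.6744897501960817 * np.sqrt(2.0)))


def _fwhm_estimate(freq: np.ndarray, smoothed: np.ndarray, baseline: float) -> float:
    peak = smoothed.max() - baseline
    half = baseline + peak / 2.0
    above = smoothed >= half
    if above.any():
        idx = np.flatnonzero(above)
        width = freq[idx[-1]] - freq[idx[0]]
        if width > 0:
            return float(width)
    return float((freq[-1] - freq[0]) / 10.0)


def _sorted_peaks(
    peaks: list[LorentzianPeak],
) -> list[LorentzianPeak]:
    # ascending shift; equal shifts -> larger amplitude first
    return sorted(peaks, key=lambda p: (p.shift_ghz, -p.amplitude))


def _finish(
    spectrum: Spectrum,
    popt: np.ndarray,
    pcov: np.ndarray | None,
    converged: bool,
    message: str = "",
) -> FitResult:
    freq = spectrum.axis.values
    k = (len(popt) - 1) // 3
    raw = [
        (float(popt[3 * i]), float(popt[3 * i + 1]), float(popt[3 * i + 2]))
        for i in range(k)
    ]
    if pcov is not None and np.all(np.isfinite(pcov)):
        err = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    else:
        err = np.full(len(popt), np.nan)
    order = sorted(range(k), key=lambda i: (raw[i][1], -raw[i][0]))
    peaks = [
        LorentzianPeak(shift_ghz=raw[i][1], fwhm_ghz=raw[i][2], amplitude=max(raw[i][0], 0.0))
        for i in order
    ]
    resid = spectrum.values - _model(freq, *popt)
    step = spectrum.axis.step_ghz
    centers = np.array([p.shift_ghz for p in peaks])
    degenerate = bool(k >= 2 and np.any(np.diff(np.sort(centers)) < step))
    return FitResult(
        peaks=peaks,
        baseline=float(popt[-1]),
        shift_err_ghz=np.array([err[3 * i + 1] for i in order]),
        fwhm_err_ghz=np.array([err[3 * i + 2] for i in order]),
        amplitude_err=np.array([err[3 * i] for i in order]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=converged,
        degenerate=degenerate,
        message=message,
    )


def _failed(spectrum: Spectrum, k: int, message: str) -> FitResult:
    freq = spectrum.axis.values
    values = spectrum.values
    baseline = float(np.median(values))
    span = freq[-1] - freq[0]
    peaks = [
        LorentzianPeak(
            shift_ghz=float(freq[int(np.argmax(values))]),
            fwhm_ghz=max(span / 10.0, 2 * spectrum.axis.step_ghz),
            amplitude=max(float(values.max() - baseline), 0.0),
        )
        for _ in range(k)
    ]
    resid = values - baseline
    return FitResult(
        peaks=_sorted_peaks(peaks),
        baseline=baseline,
        shift_err_ghz=np.full(k, np.nan),
        fwhm_err_ghz=np.full(k, np.nan),
        amplitude_err=np.full(k, np.nan),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=False,
        message=message,
    )


def _run_fit(
    spectrum: Spectrum, p0: list[float], k: int, min_fwhm_ghz: float | None = None
) -> FitResult:
    freq = spectrum.axis.values
    values = spectrum.values
    step = spectrum.axis.step_ghz
    span = freq[-1] - freq[0]
    w_lo = max(2 * step, min_fwhm_ghz or 0.0)
    amp_scale = float(values.max() - values.min())
    lo, hi = [], []
    for _ in range(k):
        lo += [0.0, freq[0], w_lo]
        hi += [max(2 * amp_scale, 1e-12), freq[-1], span]
    lo.append(values.min() - amp_scale - 1e-12)
    hi.append(values.max() + 1e-12)
    p0 = [min(max(p, l), h) for p, l, h in zip(p0, lo, hi)]
    try:
        popt, pcov = curve_fit(
            _model,
            freq,
            values,
            p0=p0,
            bounds=(lo, hi),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            maxfev=2000 * (3 * k + 1),
        )
    except (RuntimeError, ValueError) as exc:
        return _failed(spectrum, k, f"optimizer failed: {exc}")
    return _finish(spectrum, popt, pcov, converged=True)


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_lorentzian(spectrum: Spectrum) -> FitResult:
    """Fit a single Lorentzian plus constant baseline.

    A spectrum with no significant peak (initial amplitude below ~3× the
    robust noise level) returns a non-converged result instead of raising.
    """
    freq = spectrum.axis.values
    values = spectrum.values
    if freq.size < 5:
        raise InvalidParameterError("spectrum must have at least 5 points")
    smoothed = _smooth(values)
    baseline = float(np.median(smoothed))
    amp0 = float(smoothed.max() - baseline)
    sigma = _robust_noise(values)
    if amp0 <= max(3.0 * sigma, 1e-12 * max(abs(values).max(), 1.0), 0.0) or amp0 <= 0:
        return _failed(spectrum, 1, "no significant peak above the noise floor")
    c0 = float(freq[int(np.argmax(smoothed))])
    w0 = _fwhm_estimate(freq, smoothed, baseline)
    return _run_fit(spectrum, [amp0, c0, w0, baseline], 1)


def fit_multi_lorentzian(
    spectrum: Spectrum, n_peaks: int, min_fwhm_ghz: float | None = None
) -> FitResult:
    """Fit a sum of two or three Lorentzians plus constant baseline.

    Starting points are the ``n_peaks`` most prominent local maxima of the
    smoothed spectrum (prominence ≥ 5× the robust noise level); missing
    starters split the dominant peak into overlapped components.  Peaks in
    the result are sorted by shift; fits whose centers collapse within one
    axis step are flagged ``degenerate``.

    ``min_fwhm_ghz`` optionally raises the lower width bound above the
    default 2× axis step — e.g. to the instrument's spectral resolution,
    below which no genuine spectral feature can exist.
    """
    if n_peaks not in (2, 3):
        raise InvalidParameterError(f"n_peaks must be 2 or 3, got {n_peaks}")
    freq = spectrum.axis.values
    values = spectrum.values
    if 3 * n_peaks + 1 >= freq.size:
        raise InvalidParameterError("too few points for the requested model order")
    smoothed = _smooth(values)
    baseline = float(np.median(smoothed))
    sigma = _robust_noise(values)
    amp_range = float(smoothed.max() - baseline)
    if amp_range <= max(3.0 * sigma, 1e-12 * max(abs(values).max(), 1.0)):
        return _failed(spectrum, n_peaks, "no significant peak above the noise floor")

    prominence = max(5.0 * sigma, 0.02 * amp_range)
    idx, _props = signal.find_peaks(smoothed, prominence=prominence)
    idx = sorted(idx, key=lambda i: smoothed[i], reverse=True)[:n_peaks]
    w_global = _fwhm_estimate(freq, smoothed, baseline)

    starters: list[tuple[float, float, float]] = [
        (float(smoothed[i] - baseline), float(freq[i]), w_global) for i in idx
    ]
    if not starters:
        starters = [(amp_range, float(freq[int(np.argmax(smoothed))]), w_global)]
    while len(starters) < n_peaks:
        # split the dominant starter into two overlapped halves
        a, c, w = max(starters, key=lambda t: t[0])
        starters.remove((a, c, w))
        starters += [(a / 2.0, c - w / 4.0, w / 1.5), (a / 2.0, c + w / 4.0, w / 1.5)]
    w_lo = max(2 * spectrum.axis.step_ghz, min_fwhm_ghz or 0.0)
    p0: list[float] = []
    for a, c, w in sorted(starters, key=lambda t: t[1]):
        p0 += [a, c, max(w, w_lo)]
    p0.append(baseline)
    return _run_fit(spectrum, p0, n_peaks, min_fwhm_ghz=min_fwhm_ghz)


def brillouin_gain(fit: FitResult, dc_level: float) -> np.ndarray:
    """Brillouin gain per peak: fitted amplitude over the photodiode DC level."""
    if not dc_level > 0:
        raise InvalidParameterError(f"dc_level must be > 0, got {dc_level}")
    return np.array([p.amplitude for p in fit.peaks]) / dc_level


def estimate_snr(
    spectrum: Spectrum,
    fit: FitResult,
    noise_window_ghz: tuple[float, float],
) -> float:
    """SNR = fitted peak amplitude / std of the spectrum off resonance.

    The noise window must be disjoint from every fitted peak ± 3 FWHM and
    contain at least 5 samples.  A zero-variance window (noiseless input)
    raises :class:`UnboundedSNRError`.
    """
    lo, hi = noise_window_ghz
    if not hi > lo:
        raise NoiseWindowError("noise window must have positive width")
    for p in fit.peaks:
        if lo <= p.shift_ghz + 3 * p.fwhm_ghz and hi >= p.shift_ghz - 3 * p.fwhm_ghz:
            raise NoiseWindowError(
                f"noise window ({lo}, {hi}) GHz overlaps the peak at "
                f"{p.shift_ghz:.3f} GHz ± 3 FWHM"
            )
    freq = spectrum.axis.values
    sel = (freq >= lo) & (freq <= hi)
    if sel.sum() < 5:
        raise NoiseWindowError(
            f"noise window holds {int(sel.sum())} samples; at least 5 required"
        )
    noise = float(np.std(spectrum.values[sel], ddof=1))
    if noise == 0.0:
        raise UnboundedSNRError("zero noise in window; SNR is unbounded")
    amplitude = max(p.amplitude for p in fit.peaks)
    return amplitude / noise
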