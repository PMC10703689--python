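"""Detrending and Lorentzian fitting, checked against independent oracles."""

import numpy as np
import pytest

from sbsmicro import (
    FrequencyAxis,
    InvalidParameterError,
    LorentzianPeak,
    NoiseWindowError,
    Spectrum,
    UnboundedSNRError,
    brillouin_gain,
    detrend_highpass,
    estimate_snr,
    fit_lorentzian,
    fit_multi_lorentzian,
    make_spectrum,
)
from sbsmicro.fitting import FitResult, _model


def lorentz_basis(freq, c, w):
    u = (freq - c) / (w / 2.0)
    return 1.0 / (1.0 + u * u)


def grid_search_oracle(freq, values, shifts, widths):
    """Exhaustive least-squares over (shift, fwhm); amplitude and baseline
    solved by projection onto span{Lorentzian, 1} at every grid node.
    Returns (best_loss, best_shift, best_width)."""
    n = freq.size
    cs, ws = (g.ravel() for g in np.meshgrid(shifts, widths, indexing="ij"))
    u = (freq[None, :] - cs[:, None]) / (ws[:, None] / 2.0)
    basis = 1.0 / (1.0 + u * u)  # [grid, n]
    q1 = np.full(n, 1.0 / np.sqrt(n))
    along1 = basis @ q1
    perp = basis - along1[:, None] * q1[None, :]
    norms = np.linalg.norm(perp, axis=1)
    norms[norms == 0] = 1.0
    q2 = perp / norms[:, None]
    losses = values @ values - (q1 @ values) ** 2 - (q2 @ values) ** 2
    i = int(np.argmin(losses))
    return float(losses[i]), float(cs[i]), float(ws[i])


class TestDetrend:
    fs = 5000.0

    def test_constant_offset_removed(self):
        out = detrend_highpass(np.full(10_000, 7.0), self.fs, 50.0)
        assert np.abs(out).mean() < 1e-9 * 7.0

    def test_slow_drift_strongly_attenuated(self):
        # 1 Hz tone through a 50 Hz first-order zero-phase high-pass:
        # |H|^2 = (f/fc)^2/(1+(f/fc)^2) applied twice -> ~4e-4
        t = np.arange(0, 4.0, 1 / self.fs)
        x = np.sin(2 * np.pi * 1.0 * t)
        out = detrend_highpass(x, self.fs, 50.0)
        mid = slice(t.size // 4, 3 * t.size // 4)
        assert np.std(out[mid]) / np.std(x[mid]) <= 1 / 50

    def test_band_signal_preserved(self):
        t = np.arange(0, 4.0, 1 / self.fs)
        x = np.sin(2 * np.pi * 500.0 * t)
        out = detrend_highpass(x, self.fs, 50.0)
        mid = slice(t.size // 4, 3 * t.size // 4)
        # transfer magnitude at 10x cutoff, squared by filtfilt: 100/101
        assert np.std(out[mid]) / np.std(x[mid]) == pytest.approx(100 / 101, abs=0.01)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            detrend_highpass(np.zeros(100), 100.0, 50.0)


class TestSingleFit:
    def test_noiseless_recovery_is_exact(self, noiseless_water, water_peak):
        fit = fit_lorentzian(noiseless_water)
        assert fit.converged
        p = fit.peaks[0]
        assert p.shift_ghz == pytest.approx(water_peak.shift_ghz, rel=1e-6)
        assert p.fwhm_ghz == pytest.approx(water_peak.fwhm_ghz, rel=1e-6)
        assert p.amplitude == pytest.approx(water_peak.amplitude, rel=1e-6)
        assert fit.residual_rms < 1e-8 * water_peak.amplitude

    def test_flat_spectrum_flagged_not_raised(self, water_axis):
        fit = fit_lorentzian(Spectrum(axis=water_axis, values=np.zeros(100)))
        assert not fit.converged

    def test_too_few_points_rejected(self):
        ax = FrequencyAxis(4.0, 6.0, 4)
        with pytest.raises(InvalidParameterError):
            fit_lorentzian(Spectrum(axis=ax, values=np.zeros(4)))

    def test_translation_invariance(self, water_axis, water_peak):
        s0 = make_spectrum(water_axis, [water_peak], snr=38, seed=9)
        delta = 1.75
        shifted_axis = FrequencyAxis(
            water_axis.start_ghz + delta, water_axis.end_ghz + delta, water_axis.n_points
        )
        s1 = Spectrum(axis=shifted_axis, values=s0.values.copy())
        f0, f1 = fit_lorentzian(s0), fit_lorentzian(s1)
        assert f1.peaks[0].shift_ghz - f0.peaks[0].shift_ghz == pytest.approx(
            delta, abs=1e-8
        )

    def test_shift_scatter_matches_grid_ml_oracle(self, water_axis, water_peak):
        """Std of fitted shifts over noisy repeats agrees with a brute-force
        dense-grid maximum-likelihood oracle run on the same draws."""
        rng = np.random.default_rng(2024)
        freq = water_axis.values
        shifts_fit, shifts_oracle = [], []
        grid_c = np.arange(4.95, 5.05, 0.0005)
        grid_w = np.arange(0.35, 0.60, 0.01)
        for _ in range(300):
            s = make_spectrum(
                water_axis, [water_peak], snr=38, seed=int(rng.integers(2**31))
            )
            fit = fit_lorentzian(s)
            assert fit.converged
            shifts_fit.append(fit.peaks[0].shift_ghz)
            _, c, _w = grid_search_oracle(freq, s.values, grid_c, grid_w)
            shifts_oracle.append(c)
        std_fit = np.std(shifts_fit, ddof=1)
        std_oracle = np.std(shifts_oracle, ddof=1)
        assert std_fit == pytest.approx(std_oracle, rel=0.20)

    def test_least_squares_beats_grid_search(self, water_peak):
        """On coarse 50-point spectra the optimizer's loss must be <= the
        exhaustive (shift, fwhm) grid search at 0.01 GHz resolution."""
        ax = FrequencyAxis(4.0, 6.0, 50)
        for seed in (1, 2, 3):
            s = make_spectrum(ax, [water_peak], snr=25, seed=seed)
            fit = fit_lorentzian(s)
            p = fit.peaks[0]
            params = [p.amplitude, p.shift_ghz, p.fwhm_ghz, fit.baseline]
            resid = s.values - _model(ax.values, *params)
            loss_fit = float(resid @ resid)
            loss_grid, *_ = grid_search_oracle(
                ax.values,
                s.values,
                np.arange(4.0, 6.0, 0.01),
                np.arange(0.1, 1.5, 0.01),
            )
            assert loss_fit <= loss_grid * (1 + 1e-9)

    def test_precision_scales_inversely_with_snr(self, water_axis, water_peak):
        rng = np.random.default_rng(5)
        snrs = np.logspace(1, np.log10(300), 5)
        stds = []
        for snr in snrs:
            shifts = []
            for _ in range(120):
                s = make_spectrum(
                    water_axis, [water_peak], snr=snr, seed=int(rng.integers(2**31))
                )
                shifts.append(fit_lorentzian(s).peaks[0].shift_ghz)
            stds.append(np.std(shifts, ddof=1))
        slope = np.polyfit(np.log10(snrs), np.log10(stds), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)


class TestMultiFit:
    def test_noiseless_two_peak_recovery(self, water_axis):
        truth = [LorentzianPeak(5.03, 0.46, 1.0), LorentzianPeak(5.80, 0.46, 0.8)]
        s = make_spectrum(water_axis, truth, snr=np.inf)
        fit = fit_multi_lorentzian(s, 2)
        assert fit.converged and not fit.degenerate
        for got, want in zip(fit.peaks, truth):
            assert got.shift_ghz == pytest.approx(want.shift_ghz, rel=1e-4)
            assert got.fwhm_ghz == pytest.approx(want.fwhm_ghz, rel=1e-4)
            assert got.amplitude == pytest.approx(want.amplitude, rel=1e-4)

    def test_triple_peak_recovery_at_snr30(self):
        # the three mechanical components resolved inside one focal volume
        truth = [
            LorentzianPeak(5.34, 0.40, 1.0),
            LorentzianPeak(5.63, 0.40, 0.9),
            LorentzianPeak(6.63, 0.45, 0.7),
        ]
        ax = FrequencyAxis(4.5, 7.5, 150)
        rng = np.random.default_rng(17)
        for _ in range(10):
            s = make_spectrum(ax, truth, snr=30, seed=int(rng.integers(2**31)))
            fit = fit_multi_lorentzian(s, 3)
            assert fit.converged
            for got, want in zip(fit.peaks, truth):
                assert abs(got.shift_ghz - want.shift_ghz) <= 0.05

    def test_identical_centers_flag_degenerate(self, water_axis):
        truth = [LorentzianPeak(5.0, 0.46, 1.0), LorentzianPeak(5.0, 0.46, 0.5)]
        s = make_spectrum(water_axis, truth, snr=np.inf)
        fit = fit_multi_lorentzian(s, 2)
        assert fit.degenerate

    def test_peaks_sorted_by_shift(self, water_axis):
        truth = [LorentzianPeak(5.7, 0.4, 0.6), LorentzianPeak(4.5, 0.4, 1.0)]
        s = make_spectrum(water_axis, truth, snr=np.inf)
        fit = fit_multi_lorentzian(s, 2)
        shifts = [p.shift_ghz for p in fit.peaks]
        assert shifts == sorted(shifts)

    @pytest.mark.parametrize("k", [1, 4])
    def test_model_order_outside_range_rejected(self, noiseless_water, k):
        with pytest.raises(InvalidParameterError):
            fit_multi_lorentzian(noiseless_water, k)

    def test_noiseless_residual_is_machine_level(self, water_axis):
        truth = [LorentzianPeak(4.8, 0.5, 1.0), LorentzianPeak(5.6, 0.4, 0.7)]
        s = make_spectrum(water_axis, truth, snr=np.inf)
        fit = fit_multi_lorentzian(s, 2)
        assert fit.residual_rms < 1e-8


class TestGainAndSnr:
    def test_gain_is_amplitude_over_dc(self):
        fit = FitResult(peaks=[LorentzianPeak(5.0, 0.4, 0.5)], converged=True)
        assert brillouin_gain(fit, 100.0)[0] == pytest.approx(0.005)

    def test_gain_linear_in_amplitude(self):
        f1 = FitResult(peaks=[LorentzianPeak(5.0, 0.4, 0.5)], converged=True)
        f2 = FitResult(peaks=[LorentzianPeak(5.0, 0.4, 1.0)], converged=True)
        assert brillouin_gain(f2, 50.0)[0] == pytest.approx(
            2 * brillouin_gain(f1, 50.0)[0]
        )

    def test_nonpositive_dc_rejected(self):
        fit = FitResult(peaks=[LorentzianPeak(5.0, 0.4, 0.5)], converged=True)
        with pytest.raises(InvalidParameterError):
            brillouin_gain(fit, 0.0)

    def test_snr_is_amplitude_over_window_std(self):
        ax = FrequencyAxis(4.0, 9.0, 250)
        rng = np.random.default_rng(0)
        values = np.zeros(250)
        window = (ax.values >= 7.0) & (ax.values <= 9.0)
        values[window] = rng.normal(0, 0.5, window.sum())
        s = Spectrum(axis=ax, values=values)
        fit = FitResult(peaks=[LorentzianPeak(5.0, 0.459, 10.0)], converged=True)
        snr = estimate_snr(s, fit, (7.0, 9.0))
        assert snr == pytest.approx(10.0 / values[window].std(ddof=1))

    def test_zero_variance_window_is_distinct_error(self, water_peak):
        ax = FrequencyAxis(4.0, 9.0, 250)
        s = make_spectrum(ax, [water_peak], snr=np.inf)
        s.values[ax.values >= 7.0] = 0.0  # perfectly quiet noise window
        fit = fit_lorentzian(s)
        with pytest.raises(UnboundedSNRError):
            estimate_snr(s, fit, (7.0, 9.0))

    def test_window_overlapping_peak_rejected(self, water_peak):
        ax = FrequencyAxis(4.0, 9.0, 250)
        s = make_spectrum(ax, [water_peak], snr=38, seed=0)
        fit = fit_lorentzian(s)
        with pytest.raises(NoiseWindowError):
            estimate_snr(s, fit, (5.5, 9.0))

    def test_estimate_tracks_generated_snr(self, water_peak):
        # off-resonance noise window 7-9 GHz, disjoint from the 5 GHz peak
        ax = FrequencyAxis(4.0, 9.0, 250)
        rng = np.random.default_rng(31)
        estimates = []
        for _ in range(100):
            s = make_spectrum(ax, [water_peak], snr=38, seed=int(rng.integers(2**31)))
            fit = fit_lorentzian(s)
            estimates.append(estimate_snr(s, fit, (7.0, 9.0)))
        assert np.mean(estimates) == pytest.approx(38.0, rel=0.15)
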