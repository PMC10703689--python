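"""Shared fixtures: canonical water spectra and small scan geometries."""

import numpy as np
import pytest

from sbsmicro import (
    DEFAULT_AXIS,
    FrequencyAxis,
    LorentzianPeak,
    ScanGeometry,
    WATER_PEAK,
    make_spectrum,
)


@pytest.fixture
def water_axis() -> FrequencyAxis:
    return DEFAULT_AXIS


@pytest.fixture
def water_peak() -> LorentzianPeak:
    return WATER_PEAK


@pytest.fixture
def noiseless_water(water_axis, water_peak):
    return make_spectrum(water_axis, [water_peak], snr=np.inf)


@pytest.fixture
def noisy_water_factory(water_axis, water_peak):
    def _make(seed: int, snr: float = 38.0):
        return make_spectrum(water_axis, [water_peak], snr=snr, seed=seed)

    return _make


@pytest.fixture
def small_geometry() -> ScanGeometry:
    return ScanGeometry(nx=12, ny=8, nz=3, n_freq=50)
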