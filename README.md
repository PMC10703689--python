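# sbsmicro

Analysis and simulation toolkit for **pulsed stimulated-Brillouin-scattering
(SBS) microscopy** — an all-optical elastography technique that maps the
viscoelasticity of living samples by measuring the stimulated Brillouin gain
(SBG) a pump beam imprints on a counter-propagating probe.

Each pixel of an SBS image is a gain spectrum G(Ω) recorded while sweeping
the pump–probe detuning Ω across the acoustic resonance.  The resonance is
Lorentzian: its center Ω_B (the Brillouin shift) tracks the longitudinal
stiffness of the focal volume, its full width Γ_B the acoustic damping, and
its amplitude over the detector DC level the Brillouin gain G_B.  The
complex longitudinal modulus follows as

    M* = ρ (λ₁/2n)² Ω_B² (1 + i Γ_B/Ω_B).

Pulsing pump and probe at duty cycle dc while keeping average powers fixed
boosts the SNR by E = 1/dc, which is what makes low-photodamage SBS imaging
of cells and embryos possible; the package implements that arithmetic, the
spectral pipeline (high-pass detrending, 1–3-Lorentzian fitting, a
derivative-offset single/multi-peak classifier), raster-scan reconstruction
(serpentine undo, stage-delay line shift, z-plane flips), and instrument
metrology (frequency calibration, spectral/spatial resolution, shot-noise
precision scaling, scan-range fidelity).  A synthetic-data module generates
every input with known ground truth, so the whole chain is testable without
an instrument.

Intended users: instrument builders validating an SBS analysis chain,
and anyone who needs a tested reference implementation of multi-Lorentzian
Brillouin spectral analysis.

## Worked example

Simulate a noisy water calibration spectrum at the instrument's operating
point (SNR 38 at 20 ms integration), fit it, and report the pulse scheme:

```python
import numpy as np
from sbsmicro import (DEFAULT_AXIS, WATER_PEAK, PulseScheme,
                      make_spectrum, fit_lorentzian, classify_spectrum)

spec = make_spectrum(DEFAULT_AXIS, [WATER_PEAK], snr=38.0, seed=7)
fit = fit_lorentzian(spec)
peak = fit.peaks[0]
print(f"shift     {peak.shift_ghz:.4f} GHz")
print(f"linewidth {peak.fwhm_ghz*1e3:.1f} MHz")
print(f"label     {classify_spectrum(spec).label}")

scheme = PulseScheme(pulse_width_ns=40, rep_rate_mhz=1.1,
                     avg_pump_mw=13, avg_probe_mw=5)
print(f"duty cycle {scheme.duty_cycle:.3f}, enhancement {scheme.enhancement:.1f}")
print(f"equivalent CW pump {scheme.equivalent_cw_pump_mw:.0f} mW")
```

prints

```
shift     5.0017 GHz
linewidth 453.7 MHz
label     single
duty cycle 0.044, enhancement 22.7
equivalent CW pump 295 mW
```

The fitted shift lands within ~2 MHz of the true 5.000 GHz water
resonance and the linewidth within a few MHz of the true 459 MHz — the
per-spectrum precision expected at SNR 38 — and the classifier correctly
calls the spectrum a single resonance.  The pulse scheme numbers say: 40 ns
pulses at 1.1 MHz fill 4.4% of each period, so a 13 mW average pump
delivers the SNR of a 295 mW continuous-wave pump.

The same pipeline runs from the shell:

```sh
sbsmicro simulate --config run.yaml --output-dir out   # phantom -> HDF5 cube
sbsmicro fit      --config run.yaml --output-dir out --cube out/cube.h5
sbsmicro classify --config run.yaml --output-dir out --cube out/cube.h5
sbsmicro metrology --output-dir out
sbsmicro report    --output-dir out
```

producing per-pixel fit tables (CSV), parameter maps (32-bit float TIFF +
JSON sidecar) and a metrology summary; every run logs its config hash,
seed and library versions, and identical config + seed reproduce identical
outputs.

See `docs/methods.md` for the models, conventions and their rationale.

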