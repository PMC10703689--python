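"""Closed-form stimulated-Brillouin-gain (SBG) physics.

A pump and a counter-propagating probe beam interact through an acoustic
phonon field.  When their frequency difference Ω hits the Brillouin
resonance Ω_B of the medium, the probe experiences gain (SBG) or the pump
loss (SBL) with a Lorentzian line shape of full width Γ_B.  The measured
gain spectrum is

    G(Ω) = ±η · g(Ω) · l · I₁

with η the pump–probe overlap efficiency, l the interaction length and I₁
the pump intensity.  Pulsing both beams at duty cycle dc while keeping the
average powers fixed raises the peak intensity by 1/dc and therefore the
signal — hence the SNR at fixed average probe power — by an enhancement
factor E = 1/dc over the continuous-wave (CW) scheme.

The resonance parameters map onto the complex longitudinal modulus of the
medium,

    M* = ρ (λ₁ / 2n)² Ω_B² (1 + i Γ_B / Ω_B),

where ρ is the mass density, n the refractive index and λ₁ the pump
wavelength; Ω_B and Γ_B are ordinary frequencies (Hz) in this relation.

Frequencies are carried in GHz throughout the package; conversion to Hz
happens only inside :func:`longitudinal_modulus`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "InvalidParameterError",
    "LorentzianPeak",
    "GainModel",
    "PulseScheme",
    "MaterialOptics",
    "ComplexModulus",
    "lorentzian",
    "sbg_spectrum",
    "duty_cycle",
    "enhancement_factor",
    "equivalent_cw_pump",
    "longitudinal_modulus",
]


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class LorentzianPeak:
    """One Brillouin resonance.

    Parameters
    ----------
    shift_ghz
        Center frequency Ω_B in GHz.
    fwhm_ghz
        Full width at half maximum Γ_B in GHz; must be positive.
    amplitude
        Peak gain in detector-referred (dimensionless) units; non-negative.
    """

    shift_ghz: float
    fwhm_ghz: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.fwhm_ghz > 0:
            raise InvalidParameterError(
                f"fwhm_ghz must be > 0, got {self.fwhm_ghz}"
            )
        if self.amplitude < 0:
            raise InvalidParameterError(
                f"amplitude must be >= 0, got {self.amplitude}"
            )


@dataclass(frozen=True)
class GainModel:
    """Scale factors of the SBG spectrum G(Ω) = ±η g(Ω) l I₁.

    The absolute calibration constants are free parameters of the
    instrument; all default to 1 so that the model reduces to the bare
    Lorentzian sum.
    """

    eta: float = 1.0  # pump-probe overlap efficiency, 0..1
    interaction_length_um: float = 1.0  # l
    pump_intensity: float = 1.0  # I1, arbitrary intensity units

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise InvalidParameterError(f"eta must be in [0, 1], got {self.eta}")
        if not self.interaction_length_um > 0:
            raise InvalidParameterError("interaction_length_um must be > 0")
        if self.pump_intensity < 0:
            raise InvalidParameterError("pump_intensity must be >= 0")


@dataclass(frozen=True)
class PulseScheme:
    """Pulsed pump–probe timing and power budget.

    Derived quantities (duty cycle, peak powers, enhancement) follow from
    pulse width and repetition rate; average powers are those a power meter
    would read on the pulsed beam.
    """

    pulse_width_ns: float
    rep_rate_mhz: float
    avg_pump_mw: float = 0.0
    avg_probe_mw: float = 0.0

    def __post_init__(self) -> None:
        # duty_cycle() validates width/period consistency
        duty_cycle(self.pulse_width_ns, self.rep_rate_mhz)
        if self.avg_pump_mw < 0 or self.avg_probe_mw < 0:
            raise InvalidParameterError("average powers must be >= 0")

    @property
    def period_ns(self) -> float:
        return 1e3 / self.rep_rate_mhz

    @property
    def duty_cycle(self) -> float:
        return duty_cycle(self.pulse_width_ns, self.rep_rate_mhz)

    @property
    def enhancement(self) -> float:
        """SNR enhancement E = 1/dc over the CW scheme at equal averages."""
        return enhancement_factor(self.duty_cycle)

    @property
    def peak_pump_mw(self) -> float:
        return self.avg_pump_mw / self.duty_cycle

    @property
    def peak_probe_mw(self) -> float:
        return self.avg_probe_mw / self.duty_cycle

    @property
    def equivalent_cw_pump_mw(self) -> float:
        """CW pump power giving the same SNR at the same average probe."""
        return equivalent_cw_pump(self.avg_pump_mw, self.duty_cycle)


@dataclass(frozen=True)
class MaterialOptics:
    """Optical/mechanical constants needed to convert Ω_B, Γ_B into moduli."""

    refractive_index: float  # n
    mass_density_kg_m3: float  # rho
    pump_wavelength_nm: float  # lambda_1

    def __post_init__(self) -> None:
        if not self.refractive_index > 1:
            raise InvalidParameterError("refractive_index must be > 1")
        if not self.mass_density_kg_m3 > 0:
            raise InvalidParameterError("mass_density_kg_m3 must be > 0")
        if not self.pump_wavelength_nm > 0:
            raise InvalidParameterError("pump_wavelength_nm must be > 0")


@dataclass(frozen=True)
class ComplexModulus:
    """Complex longitudinal modulus M* = M' + iM'' in pascal."""

    storage_pa: float
    loss_pa: float

    @property
    def loss_tangent(self) -> float:
        """M''/M', equal to Γ_B/Ω_B for a Lorentzian resonance."""
        return self.loss_pa / self.storage_pa


# ---------------------------------------------------------------------------
# spectral line shape
# ---------------------------------------------------------------------------

def lorentzian(freq_ghz, peak: LorentzianPeak):
    """Lorentzian gain profile A / (1 + ((Ω − Ω_B)/(Γ_B/2))²).

    Accepts a scalar frequency or an array; returns the same shape.
    """
    if not peak.fwhm_ghz > 0:  # defensive: peaks normally validate themselves
        raise InvalidParameterError("fwhm_ghz must be > 0")
    f = np.asarray(freq_ghz, dtype=float)
    u = (f - peak.shift_ghz) / (peak.fwhm_ghz / 2.0)
    out = peak.amplitude / (1.0 + u * u)
    return out if out.ndim else float(out)


def sbg_spectrum(
    axis_ghz,
    peaks: Sequence[LorentzianPeak] | Iterable[LorentzianPeak],
    model: GainModel | None = None,
    sign: Literal["gain", "loss"] = "gain",
) -> np.ndarray:
    """Evaluate G(Ω) = ±η l I₁ Σ_k Lorentzian_k(Ω) on a frequency axis.

    `sign="loss"` returns the stimulated-Brillouin-loss branch, the exact
    negative of the gain branch.
    """
    axis = np.asarray(axis_ghz, dtype=float)
    if axis.size == 0:
        raise InvalidParameterError("frequency axis must be non-empty")
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise InvalidParameterError("frequency axis must be strictly increasing")
    if sign not in ("gain", "loss"):
        raise InvalidParameterError(f"sign must be 'gain' or 'loss', got {sign!r}")
    model = model or GainModel()
    total = np.zeros_like(axis)
    for pk in peaks:
        total += lorentzian(axis, pk)
    scale = model.eta * model.interaction_length_um * model.pump_intensity
    if sign == "loss":
        scale = -scale
    return scale * total


# ---------------------------------------------------------------------------
# pulse-enhancement arithmetic
# ---------------------------------------------------------------------------

def duty_cycle(pulse_width_ns: float, rep_rate_mhz: float) -> float:
    """Duty cycle dc = T_pulse / T_period.

    40 ns pulses at 1.1 MHz give dc = 0.044; width equal to the period is
    the CW limit dc = 1.  A width exceeding the period is unphysical and an
    error, never clipped.
    """
    if not pulse_width_ns > 0:
        raise InvalidParameterError("pulse_width_ns must be > 0")
    if not rep_rate_mhz > 0:
        raise InvalidParameterError("rep_rate_mhz must be > 0")
    dc = pulse_width_ns * 1e-9 * rep_rate_mhz * 1e6
    if dc > 1.0 + 1e-12:
        raise InvalidParameterError(
            f"pulse width {pulse_width_ns} ns exceeds the period "
            f"{1e3 / rep_rate_mhz:.6g} ns"
        )
    return min(dc, 1.0)


def enhancement_factor(dc: float) -> float:
    """Pulsed-scheme SNR enhancement E = 1/dc at fixed average powers."""
    if not 0.0 < dc <= 1.0:
        raise InvalidParameterError(f"duty cycle must be in (0, 1], got {dc}")
    return 1.0 / dc


def equivalent_cw_pump(avg_pump_mw: float, dc: float) -> float:
    """CW pump power with the same SNR as the pulsed scheme.

    A pulsed pump of average power P at duty cycle dc matches a CW pump of
    P/dc at equal average probe power (e.g. 13 mW at dc = 0.044 ≈ 295 mW).
    """
    if avg_pump_mw < 0:
        raise InvalidParameterError("avg_pump_mw must be >= 0")
    return avg_pump_mw * enhancement_factor(dc)


# ---------------------------------------------------------------------------
# viscoelastic moduli
# ---------------------------------------------------------------------------

def longitudinal_modulus(peak: LorentzianPeak, optics: MaterialOptics) -> ComplexModulus:
    """Complex longitudinal modulus from a Brillouin resonance.

    M' = ρ (λ₁/2n)² Ω_B²  and  M'' = M' Γ_B/Ω_B, with Ω_B, Γ_B converted
    from GHz to Hz.  Equivalently M' = ρV² with acoustic velocity
    V = λ₁Ω_B/2n.
    """
    if not peak.shift_ghz > 0:
        raise InvalidParameterError("shift_ghz must be > 0 for a modulus")
    omega_hz = peak.shift_ghz * 1e9
    gamma_hz = peak.fwhm_ghz * 1e9
    lam_m = optics.pump_wavelength_nm * 1e-9
    velocity = lam_m * omega_hz / (2.0 * optics.refractive_index)
    storage = optics.mass_density_kg_m3 * velocity * velocity
    loss = storage * gamma_hz / omega_hz
    return ComplexModulus(storage_pa=storage, loss_pa=loss)
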