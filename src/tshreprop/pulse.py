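"""Broadband Gaussian pump pulse and first-order excitation amplitudes.

The pump is modeled purely in the frequency domain by a Gaussian spectral
envelope ``E(omega) = E0 exp(-(omega - omega_L)^2 / (2 sigma^2)) p``, where
``sigma = delta_omega / (2 sqrt(ln 2))`` relates the envelope width to the
full width at half maximum ``delta_omega`` of the spectral intensity
``|E(omega)|^2``.  Because the pulse is much shorter than any nuclear
motion, the nuclei are frozen during the interaction and first-order
perturbation theory gives the pump-generated excited-state amplitudes

    c_k(0) = i d_0k(R) . E(omega_k0(R)),   k != 0,

evaluated at each sampled geometry.  These amplitudes carry both the
pump-generated populations |c_k|^2 and the pump-generated coherences
c_i* c_k between coherently excited states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import HBAR_EVFS, au_to_ev, ev_to_au
from .model import ElectronicStructurePoint

__all__ = [
    "GaussianPulse",
    "AmplitudeVector",
    "spectral_envelope",
    "fwhm_duration",
    "first_order_amplitudes",
    "normalize_excited",
]

_TWO_SQRT_LN2 = 2.0 * np.sqrt(np.log(2.0))


@dataclass(frozen=True)
class GaussianPulse:
    """Gaussian spectral envelope of a broadband pump.

    Frequencies are stored in atomic units; use :meth:`from_ev` for the
    eV interface the run configs expose.
    """

    omega_L: float  # central frequency, a.u.
    delta_omega: float  # fwhm of |E(omega)|^2, a.u.
    polarization: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    amplitude: float = 1.0

    def __post_init__(self):
        p = np.asarray(self.polarization, dtype=float)
        norm = np.linalg.norm(p)
        if norm == 0:
            raise ValueError("polarization vector must be nonzero")
        object.__setattr__(self, "polarization", p / norm)
        if self.delta_omega <= 0:
            raise ValueError("delta_omega must be positive")

    @classmethod
    def from_ev(cls, omega_L_eV, delta_omega_eV, polarization=(0, 0, 1), amplitude=1.0):
        return cls(
            omega_L=ev_to_au(omega_L_eV),
            delta_omega=ev_to_au(delta_omega_eV),
            polarization=np.asarray(polarization, dtype=float),
            amplitude=amplitude,
        )

    @property
    def sigma(self) -> float:
        """Envelope width sigma = delta_omega / (2 sqrt(ln 2)), a.u."""
        return self.delta_omega / _TWO_SQRT_LN2

    @property
    def omega_L_eV(self) -> float:
        return au_to_ev(self.omega_L)

    @property
    def delta_omega_eV(self) -> float:
        return au_to_ev(self.delta_omega)


@dataclass(frozen=True)
class AmplitudeVector:
    """Complex electronic amplitudes with an explicit convention tag.

    ``convention`` is one of ``"pump"`` (raw first-order amplitudes),
    ``"excited-normalized"`` (excited-state part normalized to 1, slot 0
    zero) or ``"repropagated"``.  For normalized vectors,
    ``t0_population`` stores the total excited population
    sum_{k>=1} |c_k(0)|^2 of the raw vector, the geometry-dependent
    ensemble weight of the full-propagation scheme.
    """

    values: np.ndarray
    convention: str = "pump"
    t0_population: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=complex))

    @property
    def populations(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    def excited_norm2(self) -> float:
        return float(np.sum(np.abs(self.values[1:]) ** 2))


def spectral_envelope(pulse: GaussianPulse, omega: float) -> np.ndarray:
    """Vector-valued spectral envelope E(omega) at frequency ``omega`` (a.u.)."""
    mag = pulse.amplitude * np.exp(
        -((omega - pulse.omega_L) ** 2) / (2.0 * pulse.sigma**2)
    )
    return mag * pulse.polarization


def fwhm_duration(pulse: GaussianPulse) -> float:
    """Fwhm in fs of the time-domain intensity |E(t)|^2.

    A Gaussian spectral envelope Fourier-transforms to a Gaussian in time;
    the intensity fwhm values in the two domains obey
    ``tau * delta_omega = 4 ln 2 * hbar`` exactly.
    """
    return 4.0 * np.log(2.0) * HBAR_EVFS / pulse.delta_omega_eV


def first_order_amplitudes(
    point: ElectronicStructurePoint, pulse: GaussianPulse
) -> AmplitudeVector:
    """Pump-generated amplitudes c_k(0) = i d_0k . E(omega_k0), k >= 1.

    Slot 0 (the ground state) is left at zero: only the excited part of
    the wave packet is propagated, so the residual ground-state amplitude
    never enters the dynamics.
    """
    n = point.energies.size
    c = np.zeros(n, dtype=complex)
    for k in range(1, n):
        E = spectral_envelope(pulse, point.transition_energies[k])
        c[k] = 1j * np.dot(point.dipole_adiabatic[0, k], E)
    return AmplitudeVector(values=c, convention="pump")


def normalize_excited(amps: AmplitudeVector) -> AmplitudeVector:
    """Normalize the excited-state part so sum_{k>=1} |c_k|^2 = 1.

    Records the pre-normalization excited population as ``t0_population``
    (the full-propagation ensemble weight ingredient).  Raises if the
    pulse excites nothing at this geometry.
    """
    tot = amps.excited_norm2()
    if tot <= 0.0:
        raise ValueError("pulse excites nothing at this geometry")
    c = amps.values.copy()
    c[0] = 0.0
    c[1:] /= np.sqrt(tot)
    return AmplitudeVector(values=c, convention="excited-normalized", t0_population=tot)
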