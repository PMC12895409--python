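"""Analytic electronic-structure models and harmonic Wigner sampling.

This module is the stand-in for an on-the-fly quantum-chemistry backend.
Electronic states are defined by diabatic model Hamiltonians (symmetric
``N_s x N_s`` potential matrices with matching gradients and dipole
matrices).  :func:`evaluate` diagonalizes the diabatic potential at a
nuclear geometry and returns the adiabatic picture needed by the surface
hopping engine: energies, eigenvectors, Hellmann-Feynman gradients,
adiabatic dipole matrix and transition energies.  Consecutive evaluations
along a trajectory are gauge-fixed with :func:`phase_align`, which flips
eigenvector signs so that the inter-step overlap matrix has a positive
diagonal (the basis continuity the local-diabatic electronic integrator
relies on).

Coordinates are mass-weighted throughout, so the nuclear Hamiltonian is
``H = P^2/2 + V(R)`` in atomic units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PhaseSpacePoint",
    "HarmonicReference",
    "DiabaticModel",
    "ElectronicStructurePoint",
    "ModelEvaluationError",
    "evaluate",
    "phase_align",
    "oscillator_strengths",
    "sample_wigner",
]

logger = logging.getLogger(__name__)


class ModelEvaluationError(RuntimeError):
    """Raised when a diabatic model returns non-finite values."""


@dataclass(frozen=True)
class PhaseSpacePoint:
    """Mass-weighted nuclear positions and momenta of one sample."""

    R: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "R", np.atleast_1d(np.asarray(self.R, dtype=float)))
        object.__setattr__(self, "P", np.atleast_1d(np.asarray(self.P, dtype=float)))
        if self.R.shape != self.P.shape:
            raise ValueError("R and P must have the same shape")


@dataclass(frozen=True)
class HarmonicReference:
    """Harmonic approximation of the ground-state minimum used for sampling.

    Parameters
    ----------
    frequencies
        Per-mode angular frequencies omega_k in atomic units, all > 0.
    reference_geometry
        Mass-weighted coordinates of the minimum (defaults to the origin).
    """

    frequencies: np.ndarray
    reference_geometry: np.ndarray | None = None

    def __post_init__(self):
        freq = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        if np.any(freq <= 0):
            raise ValueError("all frequencies must be positive")
        object.__setattr__(self, "frequencies", freq)
        ref = self.reference_geometry
        ref = np.zeros_like(freq) if ref is None else np.asarray(ref, dtype=float)
        if ref.shape != freq.shape:
            raise ValueError("reference_geometry must have one entry per mode")
        object.__setattr__(self, "reference_geometry", ref)

    @property
    def n_modes(self) -> int:
        return self.frequencies.size


@dataclass
class DiabaticModel:
    """Diabatic multi-state model: potential, gradient and dipole maps.

    ``potential(R)`` must return a symmetric ``(n_states, n_states)`` energy
    matrix, ``gradient(R)`` its derivative with shape
    ``(n_states, n_states, n_modes)``, and ``dipole(R)`` an element-wise
    symmetric ``(n_states, n_states, 3)`` matrix of dipole 3-vectors.
    State 0 is the electronic ground state.
    """

    n_states: int
    n_modes: int
    potential: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    dipole: Callable[[np.ndarray], np.ndarray]
    model_id: str = "anonymous"
    reference: HarmonicReference | None = None
    params: dict = field(default_factory=dict)


@dataclass
class ElectronicStructurePoint:
    """Adiabatic electronic structure at a single nuclear geometry.

    Attributes
    ----------
    energies
        Adiabatic energies, ascending, shape ``(n_states,)``.
    eigenvectors
        Orthogonal matrix whose columns are the adiabatic states in the
        diabatic basis.
    gradients
        Hellmann-Feynman adiabatic energy gradients, shape
        ``(n_states, n_modes)``.
    dipole_adiabatic
        Dipole matrix rotated to the adiabatic basis, shape
        ``(n_states, n_states, 3)``.
    transition_energies
        omega_k0 = E_k - E_0, shape ``(n_states,)``.
    overlap_to_previous
        Overlap matrix S = U_prev^T U_this between consecutive trajectory
        steps, set by :func:`phase_align` (None for the first step).
    """

    R: np.ndarray
    energies: np.ndarray
    eigenvectors: np.ndarray
    gradients: np.ndarray
    dipole_adiabatic: np.ndarray
    transition_energies: np.ndarray
    overlap_to_previous: np.ndarray | None = None


def _fix_column_gauge(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| component positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def evaluate(model: DiabaticModel, R: np.ndarray) -> ElectronicStructurePoint:
    """Diagonalize the diabatic potential at geometry ``R``.

    Adiabatic gradients are obtained from the Hellmann-Feynman theorem,
    ``g_i = u_i^T (dV/dR) u_i``; dipoles are rotated with the eigenvector
    matrix.  Raises :class:`ModelEvaluationError` on non-finite potential
    entries.
    """
    R = np.atleast_1d(np.asarray(R, dtype=float))
    if R.size != model.n_modes:
        raise ValueError(
            f"geometry has {R.size} coordinates, model expects {model.n_modes}"
        )
    V = np.asarray(model.potential(R), dtype=float)
    if not np.all(np.isfinite(V)):
        raise ModelEvaluationError(f"non-finite diabatic potential at R={R!r}")
    energies, U = np.linalg.eigh(V)
    U = _fix_column_gauge(U)

    dV = np.asarray(model.gradient(R), dtype=float)  # (N, N, n_modes)
    grads = np.einsum("ik,ijm,jk->km", U, dV, U)  # (N, n_modes)

    D = np.asarray(model.dipole(R), dtype=float)  # (N, N, 3)
    D_ad = np.einsum("ik,ijx,jl->klx", U, D, U)

    return ElectronicStructurePoint(
        R=R,
        energies=energies,
        eigenvectors=U,
        gradients=grads,
        dipole_adiabatic=D_ad,
        transition_energies=energies - energies[0],
    )


def phase_align(
    current: ElectronicStructurePoint,
    previous: ElectronicStructurePoint,
    warn_threshold: float = 0.5,
) -> ElectronicStructurePoint:
    """Fix the sign gauge of ``current`` against ``previous``.

    Flips eigenvector columns so that diag(S) >= 0 with
    ``S = U_prev^T U_current``; stores the aligned overlap on the returned
    point.  A diagonal overlap magnitude below ``warn_threshold`` suggests
    an unresolved (near-trivial) crossing at this step and is logged.
    """
    S = previous.eigenvectors.T @ current.eigenvectors
    signs = np.sign(np.diag(S))
    signs[signs == 0] = 1.0
    U = current.eigenvectors * signs
    S = S * signs
    small = np.abs(np.diag(S)) < warn_threshold
    if np.any(small):
        logger.warning(
            "small diagonal overlap(s) %s between consecutive steps; "
            "possible trivial crossing unresolved at this time step",
            np.flatnonzero(small).tolist(),
        )
    D_ad = np.einsum("i,ijx,j->ijx", signs, current.dipole_adiabatic, signs)
    return ElectronicStructurePoint(
        R=current.R,
        energies=current.energies,
        eigenvectors=U,
        gradients=current.gradients,
        dipole_adiabatic=D_ad,
        transition_energies=current.transition_energies,
        overlap_to_previous=S,
    )


def oscillator_strengths(point: ElectronicStructurePoint) -> np.ndarray:
    """Length-gauge oscillator strengths f_0a = (2/3) omega_a0 |d_0a|^2.

    Returns one value per excited state a = 1..N_s-1.  Raises if any
    transition energy is non-positive (degenerate ground/excited pair).
    """
    omega = point.transition_energies[1:]
    if np.any(omega <= 0):
        raise ValueError("non-positive transition energy: degenerate states")
    d0a = point.dipole_adiabatic[0, 1:, :]
    return (2.0 / 3.0) * omega * np.sum(d0a**2, axis=1)


def sample_wigner(
    ref: HarmonicReference, n: int, seed: int | np.random.Generator
) -> list[PhaseSpacePoint]:
    """Draw ``n`` phase-space points from the ground-state Wigner function.

    For each harmonic mode k the T=0 vibrational ground-state Wigner
    distribution is a product of Gaussians: positions with standard
    deviation ``1/sqrt(2 omega_k)`` about the reference geometry and
    momenta with standard deviation ``sqrt(omega_k/2)``, independent.
    Deterministic for a given integer seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = ref.frequencies
    Q = rng.normal(ref.reference_geometry, 1.0 / np.sqrt(2.0 * w), size=(n, ref.n_modes))
    P = rng.normal(0.0, np.sqrt(w / 2.0), size=(n, ref.n_modes))
    return [PhaseSpacePoint(Q[i], P[i]) for i in range(n)]


def samples_to_table(samples: Sequence[PhaseSpacePoint]) -> np.ndarray:
    """Stack samples into a plain columnar array (Q..., P...) for export."""
    return np.array([np.concatenate([s.R, s.P]) for s in samples])
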