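"""Shipped model presets and config-file loading.

Three families of analytic diabatic models are provided:

* a 1D two-state linear avoided crossing (constant coupling) for closed-form
  checks of the adiabatization and gauge-fixing machinery;
* a 1D two-state scattering model with tanh diabats and a Gaussian coupling,
  bounded asymptotically, used to benchmark hopping statistics against an
  exact wave-packet reference;
* N-state linear vibronic coupling (LVC) models on mass-weighted
  coordinates,
  ``V = (sum_k omega_k^2 Q_k^2 / 2) I + diag(eps_i + kappa_i . Q)
  + offdiag(lambda_ij . Q)``, with constant-plus-linear dipole matrices,
  including a "glycine-like" preset (one ground + three excited states, two
  near-degenerate states polarized along z with different brightness and a
  brighter in-plane-polarized third state).

All preset parameters are fixture choices of this package; they emulate the
qualitative structure of a small polyatomic photoexcited by a broadband UV
pulse, not any particular molecule's ab initio surfaces.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import yaml

from .constants import ev_to_au
from .model import DiabaticModel, HarmonicReference

__all__ = [
    "lvc_model",
    "avoided_crossing_1d",
    "tanh_scattering_1d",
    "two_state_crossing",
    "glycine_like",
    "single_surface",
    "load_model",
    "model_from_config",
]


def _hash_params(kind: str, params: dict) -> str:
    blob = json.dumps({"kind": kind, **{k: np.asarray(v).tolist() if isinstance(v, (np.ndarray, list, tuple)) else v for k, v in params.items()}}, sort_keys=True)
    return f"{kind}-{hashlib.sha1(blob.encode()).hexdigest()[:10]}"


def lvc_model(
    omega,
    eps,
    kappa,
    lam,
    dip0,
    dip1=None,
    model_id: str | None = None,
) -> DiabaticModel:
    """Build a linear-vibronic-coupling diabatic model.

    Parameters
    ----------
    omega : (n_modes,) harmonic frequencies of the shared ground-state
        potential, a.u.
    eps : (n_states,) vertical energies at the reference geometry.
    kappa : (n_states, n_modes) intrastate linear tuning constants.
    lam : (n_states, n_states, n_modes) interstate linear couplings,
        symmetric with zero diagonal.
    dip0 : (n_states, n_states, 3) constant dipole matrix (element-wise
        symmetric).
    dip1 : optional (n_states, n_states, n_modes, 3) linear dipole
        expansion coefficients.
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    eps = np.asarray(eps, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    lam = np.asarray(lam, dtype=float)
    dip0 = np.asarray(dip0, dtype=float)
    n_modes, n_states = omega.size, eps.size
    if kappa.shape != (n_states, n_modes):
        raise ValueError("kappa must have shape (n_states, n_modes)")
    if lam.shape != (n_states, n_states, n_modes):
        raise ValueError("lam must have shape (n_states, n_states, n_modes)")
    if not np.allclose(lam, lam.transpose(1, 0, 2)):
        raise ValueError("lam must be symmetric in its state indices")
    if dip1 is not None:
        dip1 = np.asarray(dip1, dtype=float)
        if dip1.shape != (n_states, n_states, n_modes, 3):
            raise ValueError("dip1 must have shape (n_states, n_states, n_modes, 3)")

    eye = np.eye(n_states)

    def potential(R):
        # mass-weighted coordinates: harmonic part omega^2 Q^2 / 2
        v0 = 0.5 * np.dot(omega**2, R**2)
        V = v0 * eye + np.diag(eps + kappa @ R)
        V = V + np.einsum("ijk,k->ij", lam, R)
        return V

    def gradient(R):
        dV = np.zeros((n_states, n_states, n_modes))
        harm = omega**2 * R
        for i in range(n_states):
            dV[i, i] = harm + kappa[i]
        dV += lam
        return dV

    def dipole(R):
        D = dip0.copy()
        if dip1 is not None:
            D = D + np.einsum("ijkx,k->ijx", dip1, R)
        return D

    params = {"omega": omega, "eps": eps, "kappa": kappa, "lam": lam, "dip0": dip0}
    if dip1 is not None:
        params["dip1"] = dip1
    mid = model_id or _hash_params("lvc", params)
    return DiabaticModel(
        n_states=n_states,
        n_modes=n_modes,
        potential=potential,
        gradient=gradient,
        dipole=dipole,
        model_id=mid,
        reference=HarmonicReference(frequencies=omega),
        params={"kind": "lvc", **params},
    )


def avoided_crossing_1d(A: float = 0.01, c: float = 0.005) -> DiabaticModel:
    """1D two-state linear avoided crossing: V11 = A x, V22 = -A x, V12 = c."""

    def potential(R):
        x = R[0]
        return np.array([[A * x, c], [c, -A * x]])

    def gradient(R):
        return np.array([[[A], [0.0]], [[0.0], [-A]]])

    def dipole(R):
        return np.array(
            [[[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]], [[0.0, 0.0, 1.0], [0.0, 0.0, 0.0]]]
        )

    params = {"A": A, "c": c}
    return DiabaticModel(
        n_states=2,
        n_modes=1,
        potential=potential,
        gradient=gradient,
        dipole=dipole,
        model_id=_hash_params("avoided_crossing_1d", params),
        params={"kind": "avoided_crossing_1d", **params},
    )


def tanh_scattering_1d(
    A: float = 0.01, B: float = 1.6, c: float = 0.005, w: float = 1.0
) -> DiabaticModel:
    """Bounded 1D crossing: V11 = A tanh(Bx), V22 = -V11, V12 = c exp(-w x^2).

    Asymptotically flat diabats make this suitable for scattering
    (transmission-probability) benchmarks against an exact wave packet.
    """

    def potential(R):
        x = R[0]
        v = A * np.tanh(B * x)
        return np.array([[v, c * np.exp(-w * x * x)], [c * np.exp(-w * x * x), -v]])

    def gradient(R):
        x = R[0]
        dv = A * B / np.cosh(B * x) ** 2
        dc = -2.0 * w * x * c * np.exp(-w * x * x)
        return np.array([[[dv], [dc]], [[dc], [-dv]]])

    def dipole(R):
        return np.zeros((2, 2, 3))

    params = {"A": A, "B": B, "c": c, "w": w}
    return DiabaticModel(
        n_states=2,
        n_modes=1,
        potential=potential,
        gradient=gradient,
        dipole=dipole,
        model_id=_hash_params("tanh_scattering_1d", params),
        params={"kind": "tanh_scattering_1d", **params},
    )


def two_state_crossing() -> DiabaticModel:
    """Two-mode LVC fixture with a ground state and two coupled excited states.

    Vertical excitation energies 6.80 and 7.62 eV (gap 0.82 eV, electronic
    coherence period ~5 fs), opposite tuning constants so the excited-state
    gap varies strongly over the Wigner sample and avoided crossings are
    reached within the propagation window.  Transition dipoles from the
    ground state are both z-polarized with a 1:2 magnitude ratio (weak and
    bright state); the excited-excited transition dipole is large and
    x-polarized.
    """
    omega = [0.010, 0.008]
    eps = [0.0, 0.25, 0.28]
    kappa = [[0.0, 0.0], [0.0015, 0.0007], [-0.0015, 0.0009]]
    lam = np.zeros((3, 3, 2))
    lam[1, 2, 1] = lam[2, 1, 1] = 0.0008
    dip0 = np.zeros((3, 3, 3))
    dip0[0, 0] = [0.0, 0.0, 0.4]
    dip0[1, 1] = [0.2, 0.0, 0.5]
    dip0[2, 2] = [-0.1, 0.0, 1.0]
    dip0[0, 1] = dip0[1, 0] = [0.0, 0.0, 0.3]
    dip0[0, 2] = dip0[2, 0] = [0.0, 0.0, 0.6]
    dip0[1, 2] = dip0[2, 1] = [0.8, 0.0, 0.0]
    dip1 = np.zeros((3, 3, 2, 3))
    dip1[0, 1, 0, 2] = dip1[1, 0, 0, 2] = 0.002
    dip1[0, 2, 0, 2] = dip1[2, 0, 0, 2] = -0.003
    return lvc_model(omega, eps, kappa, lam, dip0, dip1, model_id="two-state-crossing")


def glycine_like() -> DiabaticModel:
    """Three-mode LVC fixture with one ground and three excited states.

    Mimics the qualitative electronic structure of a small amino acid: two
    close-lying excited states (6.70 and 7.40 eV) with z-polarized, weak and
    moderate transition dipoles, and a brighter third state at 8.60 eV
    polarized in the x-y plane.  Oscillator strengths at the reference
    geometry are roughly 1 : 5 : 24, so a stratified (energy-windowed)
    stochastic ensemble is needed for balanced sampling.
    """
    omega = [0.012, 0.009, 0.006]
    eps = [0.0, ev_to_au(6.70), ev_to_au(7.40), ev_to_au(8.60)]
    kappa = [
        [0.0, 0.0, 0.0],
        [0.0014, 0.0006, 0.0003],
        [-0.0015, 0.0008, 0.0003],
        [0.0010, -0.0010, 0.0006],
    ]
    lam = np.zeros((4, 4, 3))
    lam[1, 2, 1] = lam[2, 1, 1] = 0.0008
    lam[2, 3, 2] = lam[3, 2, 2] = 0.0009
    lam[1, 3, 0] = lam[3, 1, 0] = 0.0003
    dip0 = np.zeros((4, 4, 3))
    dip0[0, 0] = [0.0, 0.0, 0.35]
    dip0[1, 1] = [0.15, 0.0, 0.55]
    dip0[2, 2] = [-0.10, 0.0, 0.95]
    dip0[3, 3] = [0.30, 0.25, 0.40]
    dip0[0, 1] = dip0[1, 0] = [0.0, 0.0, 0.25]
    dip0[0, 2] = dip0[2, 0] = [0.0, 0.0, 0.55]
    dip0[0, 3] = dip0[3, 0] = [0.85, 0.65, 0.0]
    dip0[1, 2] = dip0[2, 1] = [0.80, 0.0, 0.0]
    dip0[1, 3] = dip0[3, 1] = [0.0, 0.30, 0.0]
    dip0[2, 3] = dip0[3, 2] = [0.30, 0.0, 0.0]
    dip1 = np.zeros((4, 4, 3, 3))
    dip1[0, 1, 0, 2] = dip1[1, 0, 0, 2] = 0.0025
    dip1[0, 2, 0, 2] = dip1[2, 0, 0, 2] = -0.0020
    return lvc_model(omega, eps, kappa, lam, dip0, dip1, model_id="glycine-like")


def single_surface(n_states: int = 3, gap_ev: float = 0.8) -> DiabaticModel:
    """Uncoupled LVC model (zero interstate coupling): hop-free by design.

    Every state shares the same harmonic surface shifted by constant
    energies, so trajectories never hop and electronic populations are
    conserved; used to exercise the no-hop exactness of repropagation.
    """
    omega = [0.010, 0.008]
    eps = [0.0] + [ev_to_au(6.8 + gap_ev * k) for k in range(n_states - 1)]
    kappa = np.zeros((n_states, 2))
    lam = np.zeros((n_states, n_states, 2))
    dip0 = np.zeros((n_states, n_states, 3))
    for a in range(1, n_states):
        dip0[0, a] = dip0[a, 0] = [0.0, 0.0, 0.3 + 0.2 * a]
        dip0[a, a] = [0.1 * a, 0.0, 0.5]
    if n_states >= 3:
        dip0[1, 2] = dip0[2, 1] = [0.6, 0.0, 0.0]
    return lvc_model(omega, eps, kappa, lam, dip0, model_id=f"single-surface-{n_states}")


_PRESETS = {
    "avoided_crossing_1d": avoided_crossing_1d,
    "tanh_scattering_1d": tanh_scattering_1d,
    "two_state_crossing": two_state_crossing,
    "glycine_like": glycine_like,
    "single_surface": single_surface,
}


def model_from_config(cfg: dict) -> DiabaticModel:
    """Build a model from a config mapping.

    Either ``{"preset": name, **kwargs}`` or an explicit
    ``{"kind": "lvc", "omega": [...], "eps": [...], ...}`` definition.
    """
    cfg = dict(cfg)
    if "preset" in cfg:
        name = cfg.pop("preset")
        if name not in _PRESETS:
            raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
        return _PRESETS[name](**cfg)
    kind = cfg.pop("kind", "lvc")
    if kind == "lvc":
        return lvc_model(
            cfg["omega"],
            cfg["eps"],
            cfg["kappa"],
            cfg["lam"],
            cfg["dip0"],
            cfg.get("dip1"),
            model_id=cfg.get("model_id"),
        )
    raise KeyError(f"unknown model kind {kind!r}")


def load_model(path) -> DiabaticModel:
    """Load a model definition from a YAML config file."""
    with open(path) as fh:
        return model_from_config(yaml.safe_load(fh))
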