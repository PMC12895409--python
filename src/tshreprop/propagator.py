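"""Single-trajectory surface-hopping engine.

One quantum-classical trajectory couples

* classical nuclei, advanced with velocity Verlet on the gradient of the
  single *active* adiabatic surface b(t);
* quantum electronic amplitudes, advanced by integrating the electronic
  TDSE in a *local diabatic* basis: the adiabatic bases of consecutive
  steps are connected by the Loewdin-orthogonalized overlap matrix
  ``T = S (S^T S)^(-1/2)``, the Hamiltonian is interpolated linearly across
  a number of substeps in that basis, and the resulting product of unitary
  substep propagators is applied (and stored, so the electronic dynamics
  can later be replayed with different initial amplitudes);
* stochastic hops between surfaces with probabilities obtained from the
  population flux out of the active state, apportioned among the states
  whose population grew; accepted hops rescale the momentum uniformly to
  conserve total energy, energetically forbidden ones are frustrated
  (no hop, momentum untouched);
* an optional per-trajectory decoherence correction (energy-based EDC, or
  a frozen-Gaussian surrogate of the projected-forces-and-momenta scheme)
  damping inactive amplitudes.

Every quantity the electronic replay needs (energies, step propagators,
active-state sequence, kinetic energies, velocity-projected forces,
adiabatic dipoles) is recorded per step in :class:`TrajectoryRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ev_to_au, fs_to_au
from .model import (
    DiabaticModel,
    ElectronicStructurePoint,
    ModelEvaluationError,
    PhaseSpacePoint,
    evaluate,
    phase_align,
)

__all__ = [
    "PropagatorConfig",
    "DecoherenceConfig",
    "DecoherenceState",
    "TrajectoryState",
    "TrajectoryRecord",
    "HopEvent",
    "nuclear_step",
    "interval_propagator",
    "step_propagator",
    "electronic_step",
    "hop_probabilities",
    "attempt_hop",
    "apply_decoherence",
    "propagate_trajectory",
    "trajectory_rng",
]


@dataclass(frozen=True)
class PropagatorConfig:
    """Propagation parameters (user units: fs and eV)."""

    dt_fs: float = 0.3
    n_substeps: int = 51
    t_final_fs: float = 14.1
    energy_tolerance_ev: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")

    @property
    def dt_au(self) -> float:
        return fs_to_au(self.dt_fs)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_final_fs / self.dt_fs))

    @property
    def energy_tolerance_au(self) -> float:
        return ev_to_au(self.energy_tolerance_ev)


@dataclass(frozen=True)
class DecoherenceConfig:
    """Decoherence-correction selection and parameters (atomic units).

    ``scheme`` is ``"none"``, ``"edc"`` (energy-based correction with
    kinetic constant ``edc_C``) or ``"pfm"`` (frozen-Gaussian surrogate of
    the projected-forces-and-momenta correction, with Gaussian width
    parameter ``omega_pfm`` and inactive-population threshold ``eta``).
    """

    scheme: str = "pfm"
    omega_pfm: float = 4.825e-3
    eta: float = 1e-4
    edc_C: float = 0.1

    def __post_init__(self):
        if self.scheme not in ("none", "edc", "pfm"):
            raise ValueError(f"unknown decoherence scheme {self.scheme!r}")
        if self.omega_pfm <= 0:
            raise ValueError("omega_pfm must be positive")
        if not (0 <= self.eta < 1):
            raise ValueError("eta must be in [0, 1)")


@dataclass
class DecoherenceState:
    """Auxiliary per-state decoherence variables (PFM surrogate).

    ``delta_s`` and ``delta_p`` are the accumulated position and momentum
    offsets of each inactive state's auxiliary frozen Gaussian, projected
    on the velocity direction; ``damp`` is the previous cumulative overlap
    factor, so per-step damping is the ratio of consecutive overlaps.
    """

    delta_s: np.ndarray
    delta_p: np.ndarray
    damp: np.ndarray

    @classmethod
    def fresh(cls, n_states: int) -> "DecoherenceState":
        return cls(
            delta_s=np.zeros(n_states),
            delta_p=np.zeros(n_states),
            damp=np.ones(n_states),
        )

    def copy(self) -> "DecoherenceState":
        return DecoherenceState(self.delta_s.copy(), self.delta_p.copy(), self.damp.copy())


@dataclass(frozen=True)
class HopEvent:
    step: int
    time: float
    source: int
    target: int
    accepted: bool


@dataclass
class TrajectoryState:
    """Mutable state of one trajectory at a single time."""

    t: float
    point: PhaseSpacePoint
    active: int
    coeffs: np.ndarray
    es: ElectronicStructurePoint
    aux: DecoherenceState

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.dot(self.point.P, self.point.P))

    @property
    def total_energy(self) -> float:
        return self.kinetic_energy + float(self.es.energies[self.active])


@dataclass
class TrajectoryRecord:
    """Per-step history of one trajectory; the frozen support for replay.

    Arrays are indexed by time node (``n_steps + 1`` nodes); the step
    propagators ``prop`` map node k to node k+1 (``n_steps`` matrices).
    """

    t: np.ndarray  # (n+1,)
    R: np.ndarray  # (n+1, n_modes)
    P: np.ndarray  # (n+1, n_modes)
    active: np.ndarray  # (n+1,) int
    energies: np.ndarray  # (n+1, N)
    prop: np.ndarray  # (n, N, N) complex step propagators
    dipole: np.ndarray  # (n+1, N, N, 3)
    coeffs: np.ndarray  # (n+1, N) complex
    ekin: np.ndarray  # (n+1,)
    proj_forces: np.ndarray  # (n+1, N) forces projected on the velocity dir
    hops: list[HopEvent] = field(default_factory=list)
    valid: bool = True
    invalid_reason: str = ""
    model_id: str = ""
    seed: int | None = None
    dt_fs: float = 0.3
    n_substeps: int = 51
    decoherence_scheme: str = "none"

    @property
    def n_steps(self) -> int:
        return self.prop.shape[0]

    @property
    def n_states(self) -> int:
        return self.energies.shape[1]


def trajectory_rng(seed: int, index: int) -> np.random.Generator:
    """Independent, order-insensitive per-trajectory random stream."""
    return np.random.default_rng([int(seed) % (2**31), int(index)])


# ---------------------------------------------------------------------------
# nuclear motion


def nuclear_step(
    state: TrajectoryState, model: DiabaticModel, cfg: PropagatorConfig
) -> TrajectoryState:
    """One velocity-Verlet step on the active adiabatic surface.

    Returns a new state with updated geometry, momentum, time and a
    phase-aligned electronic-structure point; coefficients, active state
    and decoherence variables are carried over untouched.
    """
    dt = cfg.dt_au
    F0 = -state.es.gradients[state.active]
    if not np.all(np.isfinite(F0)):
        raise ModelEvaluationError("non-finite force")
    P_half = state.point.P + 0.5 * dt * F0
    R_new = state.point.R + dt * P_half
    es_new = phase_align(evaluate(model, R_new), state.es)
    F1 = -es_new.gradients[state.active]
    P_new = P_half + 0.5 * dt * F1
    return TrajectoryState(
        t=state.t + dt,
        point=PhaseSpacePoint(R_new, P_new),
        active=state.active,
        coeffs=state.coeffs,
        es=es_new,
        aux=state.aux,
    )


# ---------------------------------------------------------------------------
# electronic propagation


def interval_propagator(
    H0: np.ndarray, H1: np.ndarray, dt: float, n_substeps: int
) -> np.ndarray:
    """Unitary for one nuclear step with H interpolated from H0 to H1.

    The Hamiltonian is evaluated at substep midpoints, each substep is
    advanced with the exact exponential of the (real-symmetric) midpoint
    Hamiltonian, and the time-ordered product is returned.
    """
    n = n_substeps
    xs = (np.arange(n) + 0.5) / n
    Hs = (1.0 - xs)[:, None, None] * H0 + xs[:, None, None] * H1
    w, V = np.linalg.eigh(Hs)
    phases = np.exp(-1j * w * (dt / n))
    Us = np.einsum("mik,mk,mjk->mij", V, phases, V)
    G = Us[0]
    for m in range(1, n):
        G = Us[m] @ G
    return G


def step_propagator(
    es_prev: ElectronicStructurePoint,
    es_next: ElectronicStructurePoint,
    cfg: PropagatorConfig,
) -> np.ndarray:
    """Adiabatic-to-adiabatic propagator across one nuclear step.

    Built in the local diabatic basis: with S the phase-aligned overlap
    and ``T = S (S^T S)^{-1/2}`` its Loewdin orthogonalization, the start
    and end Hamiltonians are ``diag(E_prev)`` and ``T diag(E_next) T^T``;
    the returned matrix is ``T^T  Prod_m exp(-i H_m dtau)`` mapping
    amplitudes in the step-start adiabatic basis to the step-end one.
    """
    S = es_next.overlap_to_previous
    if S is None:
        raise ValueError("es_next has no overlap_to_previous; phase_align it first")
    W, sv, Vt = np.linalg.svd(S)
    if sv.min() < 1e-10:
        raise np.linalg.LinAlgError(
            "singular overlap matrix: trivial crossing unresolved at this time step"
        )
    T = W @ Vt
    H0 = np.diag(es_prev.energies)
    H1 = T @ np.diag(es_next.energies) @ T.T
    G = interval_propagator(H0, H1, cfg.dt_au, cfg.n_substeps)
    return T.T @ G


def electronic_step(
    coeffs: np.ndarray,
    es_prev: ElectronicStructurePoint,
    es_next: ElectronicStructurePoint,
    cfg: PropagatorConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate adiabatic amplitudes across one nuclear step.

    Returns ``(new_coeffs, G)`` where ``G`` is the stored step propagator.
    """
    G = step_propagator(es_prev, es_next, cfg)
    return G @ np.asarray(coeffs, dtype=complex), G


# ---------------------------------------------------------------------------
# hopping


def hop_probabilities(
    pop_before: np.ndarray, pop_after: np.ndarray, active: int
) -> np.ndarray:
    """Population-flux hop probabilities out of the active state.

    The probability to leave is the relative population loss of the active
    state over the step, ``max(0, (p_b(t) - p_b(t+dt)) / p_b(t))``,
    apportioned among the states whose population increased in proportion
    to their gains.  Sums to at most 1; all zero if the active population
    vanishes or did not decrease.
    """
    pop_before = np.asarray(pop_before, dtype=float)
    pop_after = np.asarray(pop_after, dtype=float)
    probs = np.zeros_like(pop_before)
    pb = pop_before[active]
    if pb <= 0.0:
        return probs
    loss = pb - pop_after[active]
    if loss <= 0.0:
        return probs
    gains = np.clip(pop_after - pop_before, 0.0, None)
    gains[active] = 0.0
    total_gain = gains.sum()
    if total_gain <= 0.0:
        return probs
    return (loss / pb) * gains / total_gain


def attempt_hop(
    state: TrajectoryState,
    probs: np.ndarray,
    rng: np.random.Generator,
    step: int = -1,
) -> tuple[TrajectoryState, HopEvent | None]:
    """Stochastic hop attempt with uniform momentum rescaling.

    A uniform draw selects the target state from the cumulative hop
    probabilities.  An accepted hop rescales the full momentum vector so
    total energy is conserved; a hop whose potential-energy cost exceeds
    the kinetic energy is frustrated (active state and momentum kept).
    """
    probs = np.asarray(probs, dtype=float)
    xi = rng.random()
    cum = np.cumsum(probs)
    idx = np.searchsorted(cum, xi, side="right")
    if idx >= probs.size or probs[idx] <= 0.0:
        return state, None
    target = int(idx)
    ke = state.kinetic_energy
    gap = float(state.es.energies[target] - state.es.energies[state.active])
    ke_new = ke - gap
    if ke_new < 0.0 or ke <= 0.0:
        ev = HopEvent(step, state.t, state.active, target, accepted=False)
        return state, ev
    scale = np.sqrt(ke_new / ke)
    new_point = PhaseSpacePoint(state.point.R, state.point.P * scale)
    ev = HopEvent(step, state.t, state.active, target, accepted=True)
    new_state = replace(state, point=new_point, active=target)
    return new_state, ev


# ---------------------------------------------------------------------------
# decoherence


def _renormalize(coeffs: np.ndarray, active: int) -> np.ndarray:
    """Restore unit norm by rescaling the active amplitude."""
    inactive = np.abs(coeffs) ** 2
    pb = inactive[active]
    n_in = inactive.sum() - pb
    if pb > 1e-30:
        coeffs[active] *= np.sqrt(max(1.0 - n_in, 0.0) / pb)
    else:
        norm = np.sqrt(inactive.sum())
        if norm > 0:
            coeffs /= norm
    return coeffs


def apply_decoherence(
    coeffs: np.ndarray,
    active: int,
    energies: np.ndarray,
    ekin: float,
    proj_forces: np.ndarray,
    aux: DecoherenceState,
    dcfg: DecoherenceConfig,
    dt: float,
) -> tuple[np.ndarray, DecoherenceState]:
    """Damp inactive amplitudes according to the selected scheme.

    Pure function of the per-step stored quantities (active state,
    energies, kinetic energy, velocity-projected forces), so replays along
    frozen trajectories reproduce the in-run damping exactly.  The active
    amplitude is rescaled to restore unit norm after every application.

    EDC: each inactive amplitude decays with the Granucci-Persico time
    ``tau_i = (1 + C/E_kin) / |E_i - E_b|`` (no decay when E_kin = 0).

    PFM surrogate: each populated inactive state carries an auxiliary
    trajectory offset along the velocity direction, integrated from the
    projected force difference; the amplitude is damped so its cumulative
    attenuation matches the frozen-Gaussian overlap
    ``exp[-(omega/4) ds^2 - dp^2/(4 omega)]`` (never re-cohered).
    """
    coeffs = np.asarray(coeffs, dtype=complex).copy()
    aux = aux.copy()
    n = coeffs.size
    if dcfg.scheme == "none":
        return coeffs, aux
    if dcfg.scheme == "edc":
        if ekin > 0.0:
            pref = 1.0 + dcfg.edc_C / ekin
            for i in range(n):
                if i == active:
                    continue
                gap = abs(energies[i] - energies[active])
                if gap > 0.0:
                    coeffs[i] *= np.exp(-dt * gap / pref)
        return _renormalize(coeffs, active), aux
    # pfm surrogate
    pops = np.abs(coeffs) ** 2
    w = dcfg.omega_pfm
    for i in range(n):
        if i == active:
            aux.delta_s[i] = aux.delta_p[i] = 0.0
            aux.damp[i] = 1.0
            continue
        if pops[i] < dcfg.eta:
            aux.delta_s[i] = aux.delta_p[i] = 0.0
            aux.damp[i] = 1.0
            continue
        dfor = proj_forces[i] - proj_forces[active]
        aux.delta_p[i] += dfor * dt
        aux.delta_s[i] += aux.delta_p[i] * dt
        overlap = np.exp(
            -(w / 4.0) * aux.delta_s[i] ** 2 - aux.delta_p[i] ** 2 / (4.0 * w)
        )
        factor = min(1.0, overlap / aux.damp[i])
        coeffs[i] *= factor
        aux.damp[i] = overlap
    return _renormalize(coeffs, active), aux


def _projected_forces(es: ElectronicStructurePoint, P: np.ndarray) -> np.ndarray:
    """Force of every state projected on the unit velocity vector."""
    pnorm = np.linalg.norm(P)
    if pnorm == 0.0:
        return np.zeros(es.energies.size)
    vhat = P / pnorm
    return -(es.gradients @ vhat)


# ---------------------------------------------------------------------------
# full trajectory


def propagate_trajectory(
    point: PhaseSpacePoint,
    active0: int,
    coeffs0: np.ndarray,
    model: DiabaticModel,
    cfg: PropagatorConfig,
    dcfg: DecoherenceConfig,
    rng: np.random.Generator,
) -> TrajectoryRecord:
    """Run one full surface-hopping trajectory and record its history.

    Per nuclear step: velocity-Verlet on the active surface, local-diabatic
    electronic propagation, stochastic hop attempt from the population
    flux, decoherence correction, energy-conservation check.  The record
    stores everything an electronic replay needs.  Trajectories whose total
    energy drifts beyond the configured tolerance are marked invalid.
    """
    n_steps = cfg.n_steps
    dt = cfg.dt_au
    N = model.n_states
    coeffs0 = np.asarray(coeffs0, dtype=complex)
    if coeffs0.size != N:
        raise ValueError("initial coefficient vector has wrong dimension")

    es0 = evaluate(model, point.R)
    state = TrajectoryState(
        t=0.0,
        point=point,
        active=int(active0),
        coeffs=coeffs0.copy(),
        es=es0,
        aux=DecoherenceState.fresh(N),
    )

    t_arr = np.zeros(n_steps + 1)
    R_arr = np.zeros((n_steps + 1, model.n_modes))
    P_arr = np.zeros((n_steps + 1, model.n_modes))
    act_arr = np.zeros(n_steps + 1, dtype=int)
    E_arr = np.zeros((n_steps + 1, N))
    G_arr = np.zeros((n_steps, N, N), dtype=complex)
    D_arr = np.zeros((n_steps + 1, N, N, 3))
    c_arr = np.zeros((n_steps + 1, N), dtype=complex)
    ekin_arr = np.zeros(n_steps + 1)
    fproj_arr = np.zeros((n_steps + 1, N))
    hops: list[HopEvent] = []
    valid = True
    reason = ""

    def record(k: int, st: TrajectoryState):
        t_arr[k] = st.t
        R_arr[k] = st.point.R
        P_arr[k] = st.point.P
        act_arr[k] = st.active
        E_arr[k] = st.es.energies
        D_arr[k] = st.es.dipole_adiabatic
        c_arr[k] = st.coeffs
        ekin_arr[k] = st.kinetic_energy
        fproj_arr[k] = _projected_forces(st.es, st.point.P)

    record(0, state)
    e_ref = state.total_energy
    tol = cfg.energy_tolerance_au

    for k in range(n_steps):
        try:
            new_state = nuclear_step(state, model, cfg)
            coeffs_new, G = electronic_step(state.coeffs, state.es, new_state.es, cfg)
        except (ModelEvaluationError, np.linalg.LinAlgError) as exc:
            valid = False
            reason = f"step {k}: {exc}"
            break
        probs = hop_probabilities(
            np.abs(state.coeffs) ** 2, np.abs(coeffs_new) ** 2, state.active
        )
        new_state.coeffs = coeffs_new
        new_state, ev = attempt_hop(new_state, probs, rng, step=k + 1)
        if ev is not None:
            hops.append(ev)
            if ev.accepted:
                new_state.aux = DecoherenceState.fresh(N)
        fproj = _projected_forces(new_state.es, new_state.point.P)
        new_state.coeffs, new_state.aux = apply_decoherence(
            new_state.coeffs,
            new_state.active,
            new_state.es.energies,
            new_state.kinetic_energy,
            fproj,
            new_state.aux,
            dcfg,
            dt,
        )
        G_arr[k] = G
        record(k + 1, new_state)
        if abs(new_state.total_energy - e_ref) > tol:
            valid = False
            reason = f"step {k + 1}: total energy deviated beyond tolerance"
        state = new_state

    return TrajectoryRecord(
        t=t_arr,
        R=R_arr,
        P=P_arr,
        active=act_arr,
        energies=E_arr,
        prop=G_arr,
        dipole=D_arr,
        coeffs=c_arr,
        ekin=ekin_arr,
        proj_forces=fproj_arr,
        hops=hops,
        valid=valid,
        invalid_reason=reason,
        model_id=model.model_id,
        seed=cfg.seed,
        dt_fs=cfg.dt_fs,
        n_substeps=cfg.n_substeps,
        decoherence_scheme=dcfg.scheme,
    )
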