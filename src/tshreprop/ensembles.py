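"""Initial-condition ensembles for surface hopping with pump coherences.

Three ways to turn a Wigner sample of ``N_g`` geometries into weighted
surface-hopping initial conditions:

FP (full propagation)
    One trajectory per geometry, initialized with the excited-normalized
    pump-generated amplitude vector; the initial active state is drawn
    with probability proportional to the pump-generated populations, and
    the total absorbed population acts as the geometry weight
    ``w_g = N_g^{-1} sum_k |c_k(0)|^2``.

AXE (all-excited-state ensemble)
    One trajectory per geometry *per excited state*, each initialized as a
    pure state ``c_i = delta_ia``.  The member list is independent of any
    pulse; attaching a pulse only fills the weights
    ``w_{g,a} = N_g^{-1} |c_a(0)|^2``.

SXE (stochastically selected excited-state ensemble)
    For each (geometry, state) pair, keep the member with probability
    ``p_a = f_0a / Nbar`` proportional to its oscillator strength, where
    ``Nbar`` is the per-energy-window maximum of ``f_0a`` over the sampled
    set (stratified acceptance: windows in transition energy are sampled
    independently so weak low-lying states are not starved by bright ones).
    Weights are ``w = alpha Nbar_t^{-1} |c_a(0)|^2 / p_a`` with
    ``alpha = Nbar_t / N_g``.

AXE and SXE weighted averages estimate the same expectation; the member
lists and any trajectories propagated from them are pulse-independent, so
a single propagation pass serves arbitrarily many pump pulses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import au_to_ev
from .model import DiabaticModel, PhaseSpacePoint, evaluate, oscillator_strengths
from .pulse import AmplitudeVector, GaussianPulse, first_order_amplitudes, normalize_excited

__all__ = [
    "InitialCondition",
    "EnsembleSpec",
    "build_fp",
    "build_axe",
    "build_sxe",
    "attach_pulse_weights",
    "balance",
]

logger = logging.getLogger(__name__)

_ZERO_TOL = 1e-30


@dataclass
class InitialCondition:
    """One ensemble member: identity, phase-space point and initial state."""

    g: int
    a: int | None  # initial pure excited state (None for FP members)
    point: PhaseSpacePoint
    active0: int
    coeffs0: np.ndarray  # propagation initials (delta for AXE/SXE, PGC for FP)
    t0_population: float | None = None  # sum_k |c_k(0)|^2 at this geometry
    pgc_initial: AmplitudeVector | None = None  # excited-normalized PGC vector
    weight: float | None = None
    pbar: float | None = None  # SXE acceptance probability of this member
    window: int | None = None  # SXE energy-window index

    @property
    def label(self) -> tuple:
        return (self.g, self.a)


@dataclass
class EnsembleSpec:
    """Scheme, members and bookkeeping of one nuclear ensemble."""

    scheme: str  # "fp" | "axe" | "sxe"
    n_geometries: int
    n_states: int
    members: list[InitialCondition] = field(default_factory=list)
    windows_ev: list[tuple[float, float]] | None = None
    nbar: dict[int, float] | None = None  # per-window renormalization max f
    pulse: GaussianPulse | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def alpha(self) -> float:
        """Finite-sample acceptance ratio Nbar_t / N_g (SXE)."""
        return self.n_members / self.n_geometries

    @property
    def weights(self) -> np.ndarray:
        if any(m.weight is None for m in self.members):
            raise ValueError("weights not attached; call attach_pulse_weights first")
        return np.array([m.weight for m in self.members])


def _delta(n_states: int, a: int) -> np.ndarray:
    c = np.zeros(n_states, dtype=complex)
    c[a] = 1.0
    return c


def build_fp(
    samples: list[PhaseSpacePoint],
    model: DiabaticModel,
    pulse: GaussianPulse,
    rng: np.random.Generator,
) -> EnsembleSpec:
    """Build the full-propagation ensemble for a given pump pulse.

    Geometries where the pulse excites nothing are dropped (their weight
    would be zero); the weight normalization keeps the original ``N_g``.
    """
    n_g = len(samples)
    members: list[InitialCondition] = []
    for g, pt in enumerate(samples):
        es = evaluate(model, pt.R)
        amps = first_order_amplitudes(es, pulse)
        tot = amps.excited_norm2()
        if tot <= _ZERO_TOL:
            logger.info("geometry %d dropped: pulse excites nothing", g)
            continue
        norm = normalize_excited(amps)
        pops = np.abs(amps.values) ** 2 / tot
        active0 = int(rng.choice(model.n_states, p=pops))
        members.append(
            InitialCondition(
                g=g,
                a=None,
                point=pt,
                active0=active0,
                coeffs0=norm.values.copy(),
                t0_population=tot,
                pgc_initial=norm,
                weight=tot / n_g,
            )
        )
    spec = EnsembleSpec(
        scheme="fp", n_geometries=n_g, n_states=model.n_states, members=members,
        pulse=pulse,
    )
    return spec


def build_axe(samples: list[PhaseSpacePoint], n_states: int) -> EnsembleSpec:
    """Build the pulse-independent all-excited-state ensemble.

    ``(N_s - 1) x N_g`` members, each a pure state delta_ia; weights stay
    unset until a pulse is attached.
    """
    if n_states < 2:
        raise ValueError("need at least one excited state")
    members = [
        InitialCondition(
            g=g, a=a, point=pt, active0=a, coeffs0=_delta(n_states, a)
        )
        for g, pt in enumerate(samples)
        for a in range(1, n_states)
    ]
    return EnsembleSpec(
        scheme="axe", n_geometries=len(samples), n_states=n_states, members=members
    )


def build_sxe(
    samples: list[PhaseSpacePoint],
    model: DiabaticModel,
    rng: np.random.Generator,
    windows_ev: list[tuple[float, float]] | None = None,
) -> EnsembleSpec:
    """Build the stochastically selected excited-state ensemble.

    ``windows_ev`` is a list of transition-energy intervals in eV; each
    (geometry, state) candidate is assigned to the window containing its
    vertical transition energy and accepted with probability
    ``f_0a / max_window(f)``.  Default: a single all-covering window.
    Candidates falling outside every window are never selected.
    """
    n_g = len(samples)
    n_states = model.n_states
    if windows_ev is None:
        windows_ev = [(0.0, np.inf)]

    cand: list[tuple[int, int, PhaseSpacePoint, float, int]] = []
    for g, pt in enumerate(samples):
        es = evaluate(model, pt.R)
        f = oscillator_strengths(es)
        w_ev = au_to_ev(es.transition_energies[1:])
        for a in range(1, n_states):
            widx = next(
                (i for i, (lo, hi) in enumerate(windows_ev) if lo <= w_ev[a - 1] < hi),
                None,
            )
            if widx is not None:
                cand.append((g, a, pt, float(f[a - 1]), widx))

    nbar: dict[int, float] = {}
    for _, _, _, fv, widx in cand:
        nbar[widx] = max(nbar.get(widx, 0.0), fv)

    members: list[InitialCondition] = []
    for g, a, pt, fv, widx in cand:
        if nbar[widx] <= 0.0:
            continue
        p = fv / nbar[widx]
        if rng.random() < p:
            members.append(
                InitialCondition(
                    g=g, a=a, point=pt, active0=a,
                    coeffs0=_delta(n_states, a), pbar=p, window=widx,
                )
            )
    if not members:
        raise ValueError(
            "SXE acceptance produced an empty ensemble; increase the number "
            "of sampled geometries"
        )
    return EnsembleSpec(
        scheme="sxe", n_geometries=n_g, n_states=n_states, members=members,
        windows_ev=windows_ev, nbar=nbar,
    )


def attach_pulse_weights(
    spec: EnsembleSpec, model: DiabaticModel, pulse: GaussianPulse
) -> EnsembleSpec:
    """Fill per-member weights for a pump pulse (the only pulse-dependent step).

    Computes the first-order amplitudes at each member's geometry and sets
    the scheme's weight: FP ``w_g = N_g^{-1} sum_k |c_k|^2``, AXE
    ``w_{g,a} = N_g^{-1} |c_a|^2``, SXE
    ``w = alpha Nbar_t^{-1} |c_a|^2 / p_a``.  Also stores the
    excited-normalized amplitude vector used to seed repropagation.
    Member lists are never modified, preserving pulse independence of
    AXE/SXE trajectories.
    """
    new_members = []
    n_g = spec.n_geometries
    alpha = spec.alpha
    n_t = spec.n_members
    for m in spec.members:
        es = evaluate(model, m.point.R)
        amps = first_order_amplitudes(es, pulse)
        tot = amps.excited_norm2()
        pgc = normalize_excited(amps) if tot > _ZERO_TOL else None
        if spec.scheme == "fp":
            w = tot / n_g
        elif spec.scheme == "axe":
            w = float(np.abs(amps.values[m.a]) ** 2) / n_g
        elif spec.scheme == "sxe":
            w = alpha / n_t * float(np.abs(amps.values[m.a]) ** 2) / m.pbar
        else:
            raise ValueError(f"unknown scheme {spec.scheme!r}")
        new_members.append(replace(m, weight=w, pgc_initial=pgc, t0_population=tot))
    return replace(spec, members=new_members, pulse=pulse)


def balance(
    spec: EnsembleSpec,
    valid: np.ndarray,
    rng: np.random.Generator,
) -> tuple[EnsembleSpec, np.ndarray]:
    """Balance an ensemble against discarded (invalid) trajectories.

    ``valid`` is a boolean flag per member.  For FP and SXE, additional
    valid members started in the more stable initial active states are
    randomly discarded so the initial active-state ratios before and after
    validity filtering are preserved.  For AXE, a geometry containing any
    invalid member is dropped entirely.

    Returns the balanced spec and the retained original member indices.
    """
    valid = np.asarray(valid, dtype=bool)
    if valid.size != spec.n_members:
        raise ValueError("one validity flag per member required")

    if spec.scheme == "axe":
        bad_geoms = {m.g for m, ok in zip(spec.members, valid) if not ok}
        keep = np.array(
            [ok and m.g not in bad_geoms for m, ok in zip(spec.members, valid)]
        )
        kept_idx = np.flatnonzero(keep)
    else:
        states = np.array([m.active0 for m in spec.members])
        keep = valid.copy()
        uniq = np.unique(states)
        n0 = {a: int(np.sum(states == a)) for a in uniq}
        nv = {a: int(np.sum(valid & (states == a))) for a in uniq}
        ratios = [nv[a] / n0[a] for a in uniq if n0[a] > 0]
        s = min(ratios) if ratios else 0.0
        for a in uniq:
            target = int(round(s * n0[a]))
            target = min(target, nv[a])
            pool = np.flatnonzero(valid & (states == a))
            if pool.size > target:
                drop = rng.choice(pool, size=pool.size - target, replace=False)
                keep[drop] = False
        kept_idx = np.flatnonzero(keep)

    members = [spec.members[i] for i in kept_idx]
    return replace(spec, members=members), kept_idx
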