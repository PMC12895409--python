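"""Surface-hopping engine: electronic integrator, hops, decoherence, nuclei."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from tshreprop import (
    DecoherenceConfig,
    PropagatorConfig,
    PhaseSpacePoint,
    evaluate,
    propagate_trajectory,
    trajectory_rng,
)
from tshreprop.constants import AU_TIME_FS
from tshreprop.model import DiabaticModel
from tshreprop.presets import lvc_model, tanh_scattering_1d, two_state_crossing
from tshreprop.propagator import (
    DecoherenceState,
    TrajectoryState,
    apply_decoherence,
    attempt_hop,
    hop_probabilities,
    interval_propagator,
    nuclear_step,
    step_propagator,
)


class FixedRng:
    """Deterministic stand-in for a Generator in hop tests."""

    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


def sym(rng, n):
    H = rng.normal(size=(n, n))
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# electronic integrator


def test_interval_propagator_constant_hamiltonian_equals_expm():
    rng = np.random.default_rng(0)
    H = sym(rng, 4)
    dt = 12.4
    G = interval_propagator(H, H, dt, 51)
    assert np.allclose(G, expm(-1j * H * dt), atol=1e-12)


def test_interval_propagator_rabi_oscillation():
    """Two-level constant coupling: populations follow sin^2(c t) to 1e-6."""
    c = 0.02
    H = np.array([[0.0, c], [c, 0.0]])
    dt = 1.0
    amp = np.array([1.0 + 0j, 0.0])
    G = interval_propagator(H, H, dt, 51)
    for k in range(1, 201):
        amp = G @ amp
        assert abs(abs(amp[1]) ** 2 - np.sin(c * k * dt) ** 2) < 1e-6


def test_phase_evolution_closed_form():
    """Diagonal gap: coherence Re(c0* c1) oscillates with period 2 pi / gap."""
    gap = 0.25
    H = np.diag([0.0, gap])
    dt = 0.5
    c = np.array([1.0, 1.0], dtype=complex) / np.sqrt(2.0)
    G = interval_propagator(H, H, dt, 51)
    for k in range(1, 120):
        c = G @ c
        expect = 0.5 * np.cos(gap * k * dt)
        assert (np.conj(c[0]) * c[1]).real == pytest.approx(expect, abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_interval_propagator_is_unitary(seed):
    rng = np.random.default_rng(seed)
    H0, H1 = sym(rng, 3), sym(rng, 3)
    G = interval_propagator(H0, H1, rng.uniform(0.1, 20.0), 51)
    assert np.allclose(G.conj().T @ G, np.eye(3), atol=1e-12)


def test_step_propagator_static_geometry_is_pure_phase():
    model = two_state_crossing()
    from tshreprop.model import phase_align

    es = evaluate(model, [0.3, -0.4])
    es2 = phase_align(evaluate(model, [0.3, -0.4]), es)
    cfg = PropagatorConfig()
    G = step_propagator(es, es2, cfg)
    expect = np.diag(np.exp(-1j * es.energies * cfg.dt_au))
    assert np.allclose(G, expect, atol=1e-12)


def test_step_propagator_requires_aligned_overlap():
    model = two_state_crossing()
    es = evaluate(model, [0.0, 0.0])
    es2 = evaluate(model, [0.1, 0.0])  # not phase-aligned: no overlap stored
    with pytest.raises(ValueError, match="phase_align"):
        step_propagator(es, es2, PropagatorConfig())


# ---------------------------------------------------------------------------
# hopping


def test_hop_probabilities_single_gainer():
    """Active 0.8 -> 0.6 with one gainer: leave probability 0.25."""
    p = hop_probabilities([0.8, 0.2], [0.6, 0.4], active=0)
    assert np.allclose(p, [0.0, 0.25])


def test_hop_probabilities_two_gainers_apportioned():
    """Gains 0.15 and 0.05 split the 0.25 leave probability 3:1."""
    p = hop_probabilities([0.8, 0.1, 0.1], [0.6, 0.25, 0.15], active=0)
    assert np.allclose(p, [0.0, 0.1875, 0.0625])


def test_hop_probabilities_zero_cases():
    assert np.all(hop_probabilities([0.5, 0.5], [0.6, 0.4], 0) == 0)  # no loss
    assert np.all(hop_probabilities([0.0, 1.0], [0.0, 1.0], 0) == 0)  # empty active
    total = hop_probabilities([0.9, 0.05, 0.05], [0.1, 0.5, 0.4], 0).sum()
    assert total <= 1.0 + 1e-12


def make_state(model, R, P, active, coeffs):
    return TrajectoryState(
        t=0.0,
        point=PhaseSpacePoint(R, P),
        active=active,
        coeffs=np.asarray(coeffs, dtype=complex),
        es=evaluate(model, R),
        aux=DecoherenceState.fresh(model.n_states),
    )


def test_attempt_hop_accepts_and_conserves_energy():
    model = two_state_crossing()
    state = make_state(model, [0.0, 0.0], [1.2, 0.0], 2, [0, 0, 1])
    e_before = state.total_energy
    new_state, ev = attempt_hop(state, np.array([0.0, 0.9, 0.0]), FixedRng(0.5), step=3)
    assert ev is not None and ev.accepted and ev.source == 2 and ev.target == 1
    assert new_state.active == 1
    assert new_state.total_energy == pytest.approx(e_before, rel=1e-12)
    # momentum direction preserved, magnitude rescaled
    assert new_state.point.P[0] != state.point.P[0]
    assert new_state.point.P[1] == 0.0


def test_attempt_hop_frustrated_when_kinetic_energy_insufficient():
    model = two_state_crossing()
    state = make_state(model, [0.0, 0.0], [0.01, 0.0], 1, [0, 1, 0])  # tiny KE
    new_state, ev = attempt_hop(state, np.array([0.0, 0.0, 0.9]), FixedRng(0.5))
    assert ev is not None and not ev.accepted
    assert new_state.active == 1
    assert np.array_equal(new_state.point.P, state.point.P)


def test_attempt_hop_no_event_when_draw_exceeds_probabilities():
    model = two_state_crossing()
    state = make_state(model, [0.0, 0.0], [1.2, 0.0], 2, [0, 0, 1])
    same, ev = attempt_hop(state, np.array([0.0, 0.1, 0.0]), FixedRng(0.95))
    assert ev is None and same.active == 2


# ---------------------------------------------------------------------------
# decoherence


def test_edc_damping_factor_matches_closed_form():
    dcfg = DecoherenceConfig(scheme="edc", edc_C=0.1)
    energies = np.array([0.0, 0.26])
    coeffs = np.array([0.3 + 0j, np.sqrt(1 - 0.09)])
    ekin, dt = 0.05, 12.4
    out, _ = apply_decoherence(
        coeffs, 1, energies, ekin, np.zeros(2), DecoherenceState.fresh(2), dcfg, dt
    )
    factor = np.exp(-dt * 0.26 / (1.0 + 0.1 / 0.05))
    assert abs(out[0]) == pytest.approx(0.3 * factor, rel=1e-12)
    assert np.sum(np.abs(out) ** 2) == pytest.approx(1.0, rel=1e-12)
    # no damping at zero kinetic energy
    out0, _ = apply_decoherence(
        coeffs, 1, energies, 0.0, np.zeros(2), DecoherenceState.fresh(2), dcfg, dt
    )
    assert np.array_equal(out0, coeffs)


def test_pfm_surrogate_damps_only_under_differential_force():
    dcfg = DecoherenceConfig(scheme="pfm")
    coeffs = np.array([0.5 + 0j, np.sqrt(0.75)])
    aux = DecoherenceState.fresh(2)
    # equal projected forces: auxiliary offsets stay zero, no damping
    same, aux = apply_decoherence(
        coeffs, 1, np.zeros(2), 0.1, np.array([0.3, 0.3]), aux, dcfg, 12.4
    )
    assert np.allclose(np.abs(same), np.abs(coeffs), atol=1e-14)
    # differential force: inactive amplitude monotonically damped
    aux = DecoherenceState.fresh(2)
    c = coeffs.copy()
    prev = abs(c[0])
    for _ in range(5):
        c, aux = apply_decoherence(
            c, 1, np.zeros(2), 0.1, np.array([0.01, 0.0]), aux, dcfg, 0.5
        )
        assert abs(c[0]) < prev
        prev = abs(c[0])
        assert np.sum(np.abs(c) ** 2) == pytest.approx(1.0, rel=1e-12)


def test_pfm_resets_below_population_threshold():
    dcfg = DecoherenceConfig(scheme="pfm", eta=1e-4)
    coeffs = np.array([1e-3 + 0j, np.sqrt(1 - 1e-6)])  # pop 1e-6 < eta
    aux = DecoherenceState(
        delta_s=np.array([5.0, 0.0]), delta_p=np.array([2.0, 0.0]),
        damp=np.array([0.3, 1.0]),
    )
    out, aux2 = apply_decoherence(
        coeffs, 1, np.zeros(2), 0.1, np.array([0.5, 0.0]), aux, dcfg, 12.4
    )
    assert aux2.delta_s[0] == aux2.delta_p[0] == 0.0 and aux2.damp[0] == 1.0
    assert abs(out[0]) == pytest.approx(1e-3, rel=1e-12)  # not damped


def test_decoherence_config_validation():
    with pytest.raises(ValueError):
        DecoherenceConfig(scheme="bogus")
    with pytest.raises(ValueError):
        DecoherenceConfig(omega_pfm=-1.0)
    with pytest.raises(ValueError):
        DecoherenceConfig(eta=1.5)


# ---------------------------------------------------------------------------
# nuclear motion and full trajectories


def harmonic_1d():
    return lvc_model([0.01], [0.0], [[0.0]], np.zeros((1, 1, 1)), np.zeros((1, 1, 3)))


def test_velocity_verlet_tracks_analytic_harmonic_motion():
    model = harmonic_1d()
    cfg = PropagatorConfig(dt_fs=0.05)
    state = make_state(model, [5.0], [0.0], 0, [1.0])
    omega = 0.01
    for _ in range(400):
        state = nuclear_step(state, model, cfg)
        assert state.point.R[0] == pytest.approx(
            5.0 * np.cos(omega * state.t), abs=2e-3
        )


def test_velocity_verlet_energy_drift_harmonic():
    """Energy drift below 1e-6 hartree over 1000 steps (dt = 0.1 fs).

    At this step size the bounded velocity-Verlet energy oscillation is
    ~5e-7 hartree, so the bound also caps any secular drift.
    """
    model = harmonic_1d()
    cfg = PropagatorConfig(dt_fs=0.1)
    state = make_state(model, [5.0], [0.0], 0, [1.0])
    e0 = state.total_energy
    worst = 0.0
    for _ in range(1000):
        state = nuclear_step(state, model, cfg)
        worst = max(worst, abs(state.total_energy - e0))
    assert worst < 1e-6


def test_trajectory_rng_deterministic_and_independent():
    a = trajectory_rng(7, 3).random(4)
    b = trajectory_rng(7, 3).random(4)
    c = trajectory_rng(7, 4).random(4)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_trajectory_record_shapes_and_energy_conservation(crossing_model):
    cfg = PropagatorConfig(dt_fs=0.3, t_final_fs=6.0, seed=1)
    rec = propagate_trajectory(
        PhaseSpacePoint([2.0, -3.0], [0.0, 0.0]), 2,
        np.array([0, 0, 1], dtype=complex), crossing_model, cfg,
        DecoherenceConfig(scheme="none"), trajectory_rng(1, 0),
    )
    n = cfg.n_steps
    assert rec.valid
    assert rec.t.shape == (n + 1,) and rec.prop.shape == (n, 3, 3)
    assert rec.coeffs.shape == (n + 1, 3) and rec.dipole.shape == (n + 1, 3, 3, 3)
    total = rec.ekin + rec.energies[np.arange(n + 1), rec.active]
    assert np.abs(total - total[0]).max() < cfg.energy_tolerance_au
    # norm conserved by the unitary electronic propagation (no decoherence)
    norms = np.linalg.norm(rec.coeffs, axis=1)
    assert np.abs(norms - 1.0).max() < 1e-10


def test_stored_step_propagators_are_unitary(axe_run):
    _, records = axe_run
    rec = next(iter(records.values()))
    eye = np.eye(rec.n_states)
    for G in rec.prop[:10]:
        assert np.allclose(G.conj().T @ G, eye, atol=1e-10)


def test_energy_tolerance_marks_trajectory_invalid(crossing_model):
    cfg = PropagatorConfig(dt_fs=0.3, t_final_fs=6.0, energy_tolerance_ev=1e-10, seed=1)
    rec = propagate_trajectory(
        PhaseSpacePoint([5.0, 5.0], [0.5, -0.5]), 2,
        np.array([0, 0, 1], dtype=complex), crossing_model, cfg,
        DecoherenceConfig(scheme="none"), trajectory_rng(1, 0),
    )
    assert not rec.valid
    assert "tolerance" in rec.invalid_reason


def test_transmission_matches_split_operator_reference():
    """Scattering branching agrees with an exact wave-packet oracle.

    A wave packet (x0 = -25, sigma_x = 10, k0 = 0.5) crosses the bounded
    tanh model with a wide coupling region; the exact split-operator
    reference gives lower-surface transmission 0.056, upper 0.938,
    reflection 0.007.  The hopping ensemble (300 trajectories Wigner-drawn
    from the same packet) must reproduce every branch within 0.05.
    """
    A, B, c, w = 0.01, 1.6, 0.02, 0.1
    model = tanh_scattering_1d(A=A, B=B, c=c, w=w)
    k0, x0, sx = 0.5, -25.0, 10.0

    # exact split-operator reference (diabatic basis, FFT kinetic step)
    N, L = 4096, 600.0
    x = np.linspace(-L / 2, L / 2, N, endpoint=False)
    kgrid = 2 * np.pi * np.fft.fftfreq(N, d=L / N)
    V11 = A * np.tanh(B * x)
    V12 = c * np.exp(-w * x * x)
    psi_x = (1 / (2 * np.pi * sx**2)) ** 0.25 * np.exp(
        -((x - x0) ** 2) / (4 * sx**2) + 1j * k0 * x
    )
    psi = np.stack([psi_x, np.zeros_like(psi_x)])  # lower adiabatic = diabat 1
    dt, T = 0.5, 110.0
    kin = np.exp(-0.5j * dt * kgrid**2)

    def pot_half(p):
        r = np.hypot(V11, V12)
        cos = np.cos(r * dt / 2)
        sinc = np.where(r > 0, np.sin(r * dt / 2) / np.where(r > 0, r, 1), dt / 2)
        return np.stack(
            [
                (cos - 1j * sinc * V11) * p[0] - 1j * sinc * V12 * p[1],
                -1j * sinc * V12 * p[0] + (cos + 1j * sinc * V11) * p[1],
            ]
        )

    for _ in range(int(T / dt)):
        psi = pot_half(np.fft.ifft(kin * np.fft.fft(pot_half(psi), axis=1), axis=1))
    dx = L / N
    exact = np.array(
        [
            np.sum(np.abs(psi[1]) ** 2 * (x > 0)) * dx,  # transmitted, lower
            np.sum(np.abs(psi[0]) ** 2 * (x > 0)) * dx,  # transmitted, upper
            np.sum(np.abs(psi) ** 2 * (x <= 0)) * dx,  # reflected
        ]
    )

    n_traj = 300
    rng = np.random.default_rng(21)
    xs = rng.normal(x0, sx, n_traj)
    ps = rng.normal(k0, 1 / (2 * sx), n_traj)
    cfg = PropagatorConfig(
        dt_fs=0.5 * AU_TIME_FS, n_substeps=15, t_final_fs=T * AU_TIME_FS,
        energy_tolerance_ev=50.0,
    )
    dcfg = DecoherenceConfig(scheme="none")
    counts = np.zeros(3)
    for i in range(n_traj):
        rec = propagate_trajectory(
            PhaseSpacePoint([xs[i]], [ps[i]]), 0, np.array([1.0 + 0j, 0.0]),
            model, cfg, dcfg, trajectory_rng(3, i),
        )
        if rec.R[-1, 0] > 0:
            counts[rec.active[-1]] += 1
        else:
            counts[2] += 1
    tsh = counts / n_traj
    assert np.abs(tsh - exact).max() < 0.05
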