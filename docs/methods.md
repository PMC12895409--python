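# Methods

This note documents the numerical methods, the bundled model fixtures and
the deliberate approximations of `tshreprop`. Everything quantitative
stated here is asserted by the test suite; nothing is quoted from
external calculations.

## Units and conventions

Internally everything is in Hartree atomic units; the user-facing
configuration uses eV and fs (1 Ha = 27.211386 eV, 1 a.u. of time =
0.02418884 fs, ħ = 0.6582119 eV·fs). Nuclear coordinates are
**mass-weighted**, so the nuclear Hamiltonian is `H = P²/2 + V(R)` with
unit mass and the harmonic part of every LVC model is `½ Σ_k ω_k² Q_k²`.
The ground-state Wigner distribution of mode `k` is then a Gaussian with
position spread `1/√(2ω_k)` and momentum spread `√(ω_k/2)`.

## Surface hopping engine

- **Nuclei**: velocity Verlet on the gradient of the single active
  adiabatic surface. Default step 0.3 fs; on a harmonic surface the
  energy error at 0.1 fs steps stays below 1e-6 Ha over 1000 steps
  (asserted; at 0.3 fs the bounded Verlet energy oscillation is ~5e-6 Ha,
  well inside the 0.5 eV conservation tolerance).
- **Electrons**: the time-dependent Schrödinger equation is integrated in
  a *local diabatic* basis. Consecutive adiabatic bases are connected by
  the Löwdin orthogonalization `T = S(SᵀS)^{-1/2}` of the phase-aligned
  overlap matrix `S` (computed via SVD, `T = WVᵀ`); the electronic
  Hamiltonian is interpolated linearly across 51 substeps evaluated at
  substep midpoints, each substep is the exact exponential of a real
  symmetric matrix, and the full step propagator `G = Tᵀ·Π exp(−iH_m δτ)`
  is **stored per step**. Unitarity of `G` is asserted to 1e-10 and
  constant-Hamiltonian limits reproduce `expm(−iHt)` to 1e-12 (Rabi
  populations to better than 1e-6 over 150 periods).
- **Gauge fixing**: eigenvector columns are sign-fixed deterministically
  at each evaluation and re-aligned against the previous step so
  `diag(S) ≥ 0`; diagonal overlaps below 0.5 are logged as possible
  unresolved trivial crossings, and a singular `SᵀS` aborts (and
  invalidates) the trajectory rather than silently propagating garbage.
- **Hopping**: the probability to leave the active state `b` over a step
  is the relative population loss `max(0, (p_b(t)−p_b(t+dt))/p_b(t))`,
  apportioned among the states whose population grew, in proportion to
  their gains. Accepted hops rescale the full momentum vector uniformly
  to conserve total energy; energetically forbidden hops are frustrated
  (no change). A hop-free benchmark against an exact split-operator wave
  packet on the bounded tanh scattering model reproduces all three
  scattering branches within 0.05.
- **Energy check**: trajectories whose total energy drifts more than
  0.5 eV (configurable) from its initial value are marked invalid and
  excluded by the ensemble balancing step, which preserves the initial
  active-state ratios (FP/SXE) or drops affected geometries whole (AXE).

## Decoherence corrections

Two per-trajectory corrections damp inactive amplitudes; both are *pure
functions of per-step stored quantities* (active state, adiabatic
energies, kinetic energy, velocity-projected forces), which is what makes
exact replay possible:

- **EDC** (energy-based): inactive state `i` decays with lifetime
  `τ_i = (1 + C/E_kin)/|E_i − E_b|`, `C = 0.1` Ha; no damping at zero
  kinetic energy.
- **PFM surrogate**: each populated inactive state carries auxiliary
  offsets integrated from the force difference projected on the velocity
  direction (`δp_i += (F_i−F_b)·v̂ dt`, `δs_i += δp_i dt`); the amplitude
  is damped so its cumulative attenuation follows the frozen-Gaussian
  overlap `exp[−(ω/4)δs² − δp²/(4ω)]` with `ω = 4.825e-3` and is never
  re-cohered (per-step factor capped at 1). Offsets reset on hops and
  when the state's population falls below `η = 1e-4`. This is a
  one-dimensional surrogate of a full projected-force/momentum scheme:
  only the component along the instantaneous velocity is tracked.

After either correction the active amplitude is rescaled to restore unit
norm. With either scheme the internal-consistency gap (ensemble-mean
quantum population vs active-surface fraction) on the crossing fixture
stays below 0.05 with 500 trajectories; with no correction it reaches
~0.26 (documented overcoherence).

## Pump model and ensemble schemes

The pump is treated purely in the frequency domain (the pulse is over
before the nuclei move): `c_k(0) = i d_0k(R)·E(ω_k0(R))` per geometry,
with the Gaussian envelope width `σ = Δω/(2√ln2)` defined so Δω is the
fwhm of the spectral *intensity*. The Fourier time-bandwidth product
`τ·Δω = 4 ln 2·ħ` is asserted against a numeric transform, and the
first-order amplitudes are validated to better than 1% against a
brute-force weak-field driven two-level TDSE with an explicit real
oscillating field (the agreement is ~1e-9 at amplitude 1e-4; deviations
are second order in the field).

Ensemble weights follow the scheme definitions: FP uses the total
absorbed population per geometry `w_g = N_g^{-1} Σ_k |c_k(0)|²` with the
initial surface drawn from the pump populations; AXE uses
`w_{g,a} = N_g^{-1}|c_a(0)|²`; SXE accepts (g, a) with probability
`f_0a/N̄_w` (per-window maximum oscillator strength) and uses
`w = |c_a(0)|²/(N_g p̄_a)`. AXE and SXE estimate the same expectation;
the suite asserts their weighted averages agree within Monte-Carlo error
and that acceptance counts at N_g = 2·10⁴ are proportional to oscillator
strengths within 5%. Stratification windows matter when brightness spans
an order of magnitude (as in the glycine-like fixture, f ratios ~1:5:24):
a single window starves the weak band.

## Repropagation contract

`repropagate` consumes **only** stored record data: the step propagators,
active-state sequence, energies, kinetic energies and projected forces.
It never re-draws hops. Three properties pin the implementation down:

1. **Replay identity** — repropagating from a record's own initial
   amplitudes reproduces the stored coefficient history *bit-for-bit*
   (asserted on FP, AXE and SXE records).
2. **No-hop exactness** — on the uncoupled (hop-free) preset, full
   propagation from pump amplitudes and replay of pure-state records
   agree to 1e-10 per trajectory.
3. **Scheme agreement** — with hops present, normalized ensemble means of
   populations, Re coherence and the dipole expectation from RP-AXE and
   RP-SXE track the FP reference within two Monte-Carlo standard errors
   across the coherence-decay window (500 geometries, fixed seeds; the
   observed maximum deviation is ≈1.5 combined SE).

Hops that occur while the repropagated coefficients still carry
substantial coherence (> 0.05 by default) are counted per trajectory and
logged: in that regime the frozen active-state sequence is only an
approximation, and the count is the diagnostic to watch.

## Model fixtures (package choices, not ab-initio data)

All fixture parameters are choices of this package, selected once from
physical considerations and then frozen; none were tuned against test
outcomes.

- `avoided_crossing_1d` — linear diabats ±Ax with constant coupling;
  closed-form 2×2 adiabatization oracle.
- `tanh_scattering_1d` — bounded diabats `±A tanh(Bx)` with Gaussian
  coupling; scattering benchmark vs an exact split-operator reference.
  The benchmark uses `c = 0.02, w = 0.1, k₀ = 0.5` with a wide wave
  packet (σ_x = 10) so the momentum spread (0.05) is small against the
  mean momentum and the branching (~6% stays adiabatic) is nontrivial.
- `two_state_crossing` — two-mode LVC, one ground + two coupled excited
  states at 6.80/7.62 eV. Tuning constants of opposite sign (±1.5e-3 on
  mode 0) make the excited-state gap sweep through zero across the Wigner
  ensemble, so avoided crossings are reached within the 14.1 fs window
  (~0.7 accepted hops/trajectory) and the ensemble coherence dephases in
  a few fs. Transition dipoles are z-polarized with a 1:2 ratio plus a
  geometry-dependent part.
- `glycine_like` — three-mode LVC with three excited states (6.70, 7.40,
  8.60 eV): two close-lying z-polarized states of different brightness
  and a brighter in-plane-polarized state, emulating the qualitative
  structure of a small photoexcited amino acid (brightness ratios
  ~1:5:24). Coupling magnitudes (~1e-3) were set so that diabatic
  couplings `λ·Q` over the Wigner spread (|Q| ~ 7) remain small against
  the state spacings.
- `single_surface` — identical harmonic surfaces, zero interstate
  coupling: trajectories cannot hop, making it the exactness fixture for
  repropagation.

## Reproducibility

Every stochastic element is seeded: Wigner sampling, initial-surface
draws, SXE acceptance, hop draws (per-trajectory independent streams
`default_rng([seed mod 2³¹, index])`, insensitive to propagation order),
and balancing. The pipeline manifest records seeds, per-stage trajectory
counts and a content hash over the manifest and all CSV outputs; the
suite asserts two runs of the same config produce identical hashes.

## Limitations

- Analytic diabatic models stand in for on-the-fly electronic structure;
  conclusions about a specific molecule require its own surfaces.
- The PFM-style correction is a 1D frozen-Gaussian surrogate (velocity
  direction only), not a full multi-dimensional implementation.
- Repropagation freezes the nuclear paths and the hop sequence; it is
  approximate whenever hops occur at substantial repropagated coherence
  (surfaced via the per-trajectory risky-hop count).
- Momentum rescaling after hops is uniform (no nonadiabatic-coupling
  direction is available from the stored quantities).
- The pump is strictly first order (weak field) and instantaneous
  relative to nuclear motion; the residual ground-state amplitude is
  discarded after excitation.
- Ensemble sizes used in the validation suite (100–2·10⁴ geometries
  depending on the check) are chosen for CPU-minute-scale runs;
  production studies should scale them up.
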