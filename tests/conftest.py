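"""Shared fixtures.

The expensive surface-hopping ensembles on the two-state crossing preset
are session-scoped so the acceptance tests for replay identity, scheme
agreement and internal consistency share a single propagation pass per
scheme.  All ensembles are fully deterministic (fixed seeds, per-index
RNG streams), so every test sees the same trajectories.
"""

from __future__ import annotations

import numpy as np
import pytest

from tshreprop import (
    DecoherenceConfig,
    GaussianPulse,
    PropagatorConfig,
    build_axe,
    build_fp,
    build_sxe,
    propagate_trajectory,
    sample_wigner,
    trajectory_rng,
)
from tshreprop.presets import glycine_like, single_surface, two_state_crossing

N_GEOMETRIES = 500
WIGNER_SEED = 2024
PROP_SEED = 7


def propagate_spec(spec, model, pcfg, dcfg):
    """Propagate every member of an ensemble spec; returns label->record."""
    return {
        m.label: propagate_trajectory(
            m.point, m.active0, m.coeffs0, model, pcfg, dcfg, trajectory_rng(pcfg.seed, i)
        )
        for i, m in enumerate(spec.members)
    }


@pytest.fixture(scope="session")
def crossing_model():
    return two_state_crossing()


@pytest.fixture(scope="session")
def glycine_model():
    return glycine_like()


@pytest.fixture(scope="session")
def uncoupled_model():
    return single_surface()


@pytest.fixture(scope="session")
def broadband_pulse():
    return GaussianPulse.from_ev(7.2, 2.83, (0, 0, 1))


@pytest.fixture(scope="session")
def crossing_samples(crossing_model):
    return sample_wigner(crossing_model.reference, N_GEOMETRIES, seed=WIGNER_SEED)


@pytest.fixture(scope="session")
def prop_config():
    return PropagatorConfig(seed=PROP_SEED)


@pytest.fixture(scope="session")
def pfm_config():
    return DecoherenceConfig(scheme="pfm")


@pytest.fixture(scope="session")
def fp_run(crossing_model, crossing_samples, broadband_pulse, prop_config, pfm_config):
    """Full-propagation ensemble (PGC initials) on the crossing fixture."""
    spec = build_fp(
        crossing_samples, crossing_model, broadband_pulse, np.random.default_rng(11)
    )
    records = propagate_spec(spec, crossing_model, prop_config, pfm_config)
    return spec, records


@pytest.fixture(scope="session")
def fp_run_edc(crossing_model, crossing_samples, broadband_pulse, prop_config):
    """Same FP ensemble propagated with the energy-based decoherence scheme."""
    spec = build_fp(
        crossing_samples, crossing_model, broadband_pulse, np.random.default_rng(11)
    )
    records = propagate_spec(
        spec, crossing_model, prop_config, DecoherenceConfig(scheme="edc")
    )
    return spec, records


@pytest.fixture(scope="session")
def axe_run(crossing_model, crossing_samples, prop_config, pfm_config):
    """Pulse-independent all-excited-state ensemble on the crossing fixture."""
    spec = build_axe(crossing_samples, crossing_model.n_states)
    records = propagate_spec(spec, crossing_model, prop_config, pfm_config)
    return spec, records


@pytest.fixture(scope="session")
def sxe_run(crossing_model, crossing_samples, prop_config, pfm_config):
    """Stochastically selected excited-state ensemble on the crossing fixture."""
    spec = build_sxe(crossing_samples, crossing_model, np.random.default_rng(11))
    records = propagate_spec(spec, crossing_model, prop_config, pfm_config)
    return spec, records
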