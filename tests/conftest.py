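"""Shared fixtures: expensive simulations are session-scoped and reused."""

import numpy as np
import pytest

from abscopal.cohort import CohortConfig, generate_cohort
from abscopal.engine import simulate
from abscopal.parameters import ParameterSet
from abscopal.physiology import build_default_physiology
from abscopal.radiotherapy import build_protocol


@pytest.fixture(scope="session")
def params():
    return ParameterSet.default()


@pytest.fixture(scope="session")
def physiology():
    return build_default_physiology()


@pytest.fixture(scope="session")
def arm_trajectories(params, physiology):
    """One default simulation per treatment arm (24 d, rtol 1e-6)."""
    return {
        g: simulate(params, build_protocol(g), 24.0, physiology=physiology)
        for g in ("CONTROL", "T1_RT", "T1_RT_LN_RT")
    }


@pytest.fixture(scope="session")
def clean_cohort(params):
    """Noise-free two-arm cohort at the shipped true parameters."""
    config = CohortConfig(
        groups=("CONTROL", "T1_RT"),
        n_per_group=2,
        noise_sigma=0.0,
        mouse_sigma=0.0,
        seed=11,
        true_params=params,
    )
    dataset, truth = generate_cohort(config)
    return dataset, truth


@pytest.fixture(scope="session")
def noisy_cohort(params):
    """Small noisy cohort (default noise levels, reduced n for speed)."""
    config = CohortConfig(
        n_per_group=3,
        seed=23,
        true_params=params,
    )
    dataset, truth = generate_cohort(config)
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
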