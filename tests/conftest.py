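"""Shared fixtures: small seeded synthetic cohorts reused across the suite."""

import warnings

import numpy as np
import pytest

from mlfra.config import RunConfig, SimulatorConfig
from mlfra.pipeline import extract_cohort
from mlfra.simulate import iter_cohort, make_profiles, simulate_bolus

warnings.filterwarnings("ignore", category=UserWarning)


def clean_sim_config(**overrides) -> SimulatorConfig:
    """Noise-free simulator settings (all stochastic perturbations off)."""
    defaults = dict(noise_sd_mmhg=0.0, drift_amplitude_mmhg=0.0,
                    spike_rate_per_min=0.0)
    defaults.update(overrides)
    return SimulatorConfig(**defaults)


@pytest.fixture(scope="session")
def clean_bolus():
    """One noise-free simulated bolus with planted fiducials."""
    cfg = clean_sim_config()
    prof = make_profiles(4, 3, cfg)[1]
    return simulate_bolus(prof, 1, 0, 3, cfg), prof, cfg


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free boluses across all three injury archetypes (one per pig)."""
    cfg = clean_sim_config()
    profs = make_profiles(9, 3, cfg)
    boluses = [simulate_bolus(p, i, 0, 3, cfg) for i, p in enumerate(profs)]
    return boluses, profs, cfg


@pytest.fixture(scope="session")
def small_table():
    """Feature+label table for a small noisy cohort (12 pigs x 3 boluses)."""
    cfg = RunConfig(seed=5)
    cfg.simulator.n_pigs = 12
    cfg.simulator.boluses_per_pig = 3
    table = extract_cohort(iter_cohort(12, 3, 0.5, 5, cfg.simulator), cfg)
    return table, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
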