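"""Shared fixtures: small synthetic cohorts and helper constructors."""

import numpy as np
import pytest

from dynstates.synthetic import GeneratorConfig, generate_cohort


def one_hot(path: np.ndarray, n_states: int) -> np.ndarray:
    """Hard path -> one-hot responsibility matrix."""
    gamma = np.zeros((path.size, n_states))
    gamma[np.arange(path.size), path] = 1.0
    return gamma


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (6 states, 10 regions, 8+8 subjects, no group effect)."""
    cfg = GeneratorConfig(
        n_regions=10, n_subjects_per_group=(8, 8), group_effect=None, seed=42
    )
    subjects, clinical, truth = generate_cohort(cfg)
    return cfg, subjects, clinical, truth


@pytest.fixture(scope="session")
def effect_cohort():
    """A default-effect cohort at reduced dimensionality for statistics tests."""
    cfg = GeneratorConfig(n_regions=8, seed=7)
    subjects, clinical, truth = generate_cohort(cfg)
    return cfg, subjects, clinical, truth
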