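"""Shared fixtures: calibrated population model and deterministic cohorts.

Cohorts are generated programmatically (no stored fixture data); seeds are
fixed so every run sees identical cases.
"""

import numpy as np
import pytest

from lvatlas.cohort import (FRAMES, PopulationModel, default_population_model,
                            generate_paired_cohort)

COHORT_SEED = 20130913


@pytest.fixture(scope="session")
def pop():
    return default_population_model()


@pytest.fixture(scope="session")
def paired46(pop):
    """The standard 46-case calibrated paired cohort."""
    return generate_paired_cohort(pop, 46, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def paired12(pop):
    """A small paired cohort for cheap end-to-end tests."""
    return generate_paired_cohort(pop, 12, seed=COHORT_SEED + 1)


def make_null_model(pop, param_sd=0.03, noise_sd=0.0):
    """Population with no protocol effect (delta = 0, s = 1)."""
    p = pop.n_parameters
    return PopulationModel(
        prolate=pop.prolate, grid_shape=pop.grid_shape, mu_max=pop.mu_max,
        mean={fr: pop.mean[fr].copy() for fr in FRAMES},
        param_sd={fr: np.full(p, param_sd) for fr in FRAMES},
        bias_delta={fr: np.zeros(p) for fr in FRAMES},
        bias_scale={fr: np.ones(p) for fr in FRAMES},
        noise_sd={fr: np.full(p, noise_sd) for fr in FRAMES},
        name="null",
    )


@pytest.fixture(scope="session")
def null_pop(pop):
    return make_null_model(pop)
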