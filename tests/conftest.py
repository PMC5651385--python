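"""Shared fixtures: small cohorts and the two 50-iteration reference experiments."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from voxelbma import (
    SyntheticCohortSpec,
    generate_cohort,
    run_experiment,
)

# Study-scale conditions: 32 patients / 36 controls, 500 voxels, 10%
# discriminative. The strong arm uses a standardized shift d = 2 (patients
# lower); the null arm is the identical cohort recipe with d = 0. Both share
# subjects and iteration seeds so their fold allocations are paired.
STRONG_SPEC = SyntheticCohortSpec(effect_size=2.0, seed=11)
NULL_SPEC = SyntheticCohortSpec(effect_size=0.0, seed=11)
N_ITERATIONS = 50
BASE_SEED = 100


@pytest.fixture(scope="session")
def strong_cohort():
    return generate_cohort(STRONG_SPEC)


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(NULL_SPEC)


@pytest.fixture(scope="session")
def strong_experiment(strong_cohort):
    table, _ = strong_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_experiment(table, n_iterations=N_ITERATIONS, base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def null_experiment(null_cohort):
    table, _ = null_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_experiment(table, n_iterations=N_ITERATIONS, base_seed=BASE_SEED)


@pytest.fixture
def tiny_separable():
    """Small, strongly separated cohort for fast ensemble-level tests."""
    spec = SyntheticCohortSpec(
        n_patients=10, n_controls=12, n_voxels=20,
        discriminative_fraction=0.2, effect_size=3.0, seed=5,
    )
    return generate_cohort(spec)
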