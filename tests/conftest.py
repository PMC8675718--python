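"""Shared fixtures.

The expensive fixtures are session-scoped: the five default-cohort pipeline
runs (seeds 0-4) back the end-to-end subtype-recovery, reconstruction,
fidelity-separation and perturbation checks; the null cohort backs the
label-leakage guard.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellmatch import ModelConfig, SemiSupervisedVAE, SynthSpec, generate_cohort
from cellmatch.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_runs():
    """Full pipeline on the default synthetic cohort for seeds 0-4."""
    runs = {}
    for seed in range(5):
        cohort = generate_cohort(SynthSpec(seed=seed))
        runs[seed] = (cohort, run_pipeline(cohort, seed=seed, epochs=200))
    return runs


@pytest.fixture(scope="session")
def run0(default_runs):
    return default_runs[0]


@pytest.fixture(scope="session")
def null_run():
    """Pipeline on a cohort with zero subtype signal (permutation null)."""
    spec = SynthSpec(prototype_separation=0.0, alteration_enrichment=0.0,
                     seed=123)
    cohort = generate_cohort(spec)
    return cohort, run_pipeline(cohort, seed=123, epochs=200)


@pytest.fixture
def tiny_model():
    """Small untrained model for shape/gradient tests."""
    cfg = ModelConfig(n_features=6, n_subtypes=3, encoder_hidden=(5,), seed=7)
    return SemiSupervisedVAE(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
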