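"""Shared fixtures: small simulated cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from clonescar.simulate import SimConfig, simulate_cohort, simulate_null_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four-mouse biased cohort without count matrices (fast)."""
    cfg = SimConfig(
        n_mice=4,
        cells_per_sc_dataset=300,
        make_count_matrices=False,
        seed=3,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sc_dataset():
    """One single-cell dataset with a count matrix and uniform populations."""
    cfg = SimConfig(
        n_mice=1,
        founders_per_mouse=400,
        cells_per_sc_dataset=600,
        seed=5,
    )
    cohort = simulate_null_cohort(cfg)
    return cohort.sc["m01"]


@pytest.fixture(scope="session")
def recovery_cohort():
    """Biased cohort with heavy-tailed clone sizes for lineage recovery.

    Clone sizes are chosen so the largest clones contribute enough sampled
    cells to both mature compartments for the binomial test to have
    essentially full power.
    """
    cfg = SimConfig(
        founders_per_mouse=2000,
        clone_size_log_mean=2.5,
        clone_size_log_sd=2.2,
        cells_per_sc_dataset=4000,
        make_count_matrices=False,
        seed=42,
    )
    return simulate_cohort(cfg)
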