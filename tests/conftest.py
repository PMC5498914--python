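"""Shared fixtures: small synthetic records and feature tables.

Everything is generated programmatically with fixed seeds so the suite is
deterministic and self-contained.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctglearn import (
    CohortSpec,
    GeneratorParams,
    LabelledDataset,
    build_feature_table,
    generate_cohort,
)
from ctglearn.synthetic import case_params


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def gaussian_blobs():
    """Two well-separated 13-feature Gaussian classes, 60/300 split —
    a fast stand-in for an extracted feature table."""
    rng = np.random.default_rng(42)
    n_ctrl, n_case, d = 300, 60, 13
    x_ctrl = rng.normal(0.0, 1.0, size=(n_ctrl, d))
    x_case = rng.normal(0.0, 1.0, size=(n_case, d))
    x_case[:, :4] += 2.5  # informative shift on the first four features
    features = np.vstack([x_ctrl, x_case])
    labels = np.concatenate([np.zeros(n_ctrl, int), np.ones(n_case, int)])
    return LabelledDataset(features, labels)


@pytest.fixture(scope="session")
def small_cohort_table():
    """Feature table of a 40-control / 15-case synthetic cohort with 6-min
    records — large enough for CV, small enough to extract in seconds."""
    spec = CohortSpec(n_controls=40, n_cases=15, duration_min=6.0, seed=11)
    records, _, _ = generate_cohort(spec)
    return build_feature_table(records)


@pytest.fixture
def quiet_params():
    """Generator parameters with every stochastic source switched off."""
    return GeneratorParams(
        baseline_drift_sd=0.0, stv_level=0.0, accel_rate=0.0, decel_rate=0.0,
        gap_rate=0.0, noise_sd=0.0,
    )


@pytest.fixture
def default_case_params():
    return case_params()
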