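"""Shared fixtures and helpers for the test suite.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from asapqc.acquisition import process_acquisition
from asapqc.repeatability import FeatureMatrix
from asapqc.simulate import (
    AcquisitionConfig,
    generate_cohort,
    two_batch_design,
)


@pytest.fixture
def small_grid() -> np.ndarray:
    """A reduced m/z grid for tests that do not need all 991 bins."""
    return np.arange(10.0, 210.0, 1.0)


def process_cohort(two_day: bool, seed: int) -> FeatureMatrix:
    """Run the full simulate -> process chain for one cohort arm."""
    design = two_batch_design(two_day=two_day, rng_seed=seed)
    streams, _, _ = generate_cohort(design, AcquisitionConfig(rng_seed=seed))
    spectra = [
        process_acquisition(s, provenance=s.annotations["metadata"]).averaged
        for s in streams
    ]
    return FeatureMatrix.from_spectra(spectra)


def planted_batch_matrix(seed: int, n_per_batch: int = 12, n_bins: int = 300):
    """Feature matrix with a rank-1 batch component orthogonal to biology.

    Two batches of ``n_per_batch`` samples, sample types balanced 50/50
    within each batch; a unit-norm type axis, a 1.5x batch axis orthogonal
    to it, and iid Gaussian bin noise (sd 0.05).
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_batch
    half = n_per_batch // 2
    batch = np.array(["b1"] * n_per_batch + ["b2"] * n_per_batch)
    stype = np.array((["t1"] * half + ["t2"] * (n_per_batch - half)) * 2)
    u_type = rng.normal(0, 1, n_bins)
    u_type /= np.linalg.norm(u_type)
    u_batch = rng.normal(0, 1, n_bins)
    u_batch -= (u_batch @ u_type) * u_type
    u_batch /= np.linalg.norm(u_batch)
    X = (
        np.where(stype == "t1", 1.0, -1.0)[:, None] * u_type
        + 1.5 * np.where(batch == "b1", 1.0, -1.0)[:, None] * u_batch
        + rng.normal(0, 0.05, (n, n_bins))
    )
    return X, batch, stype
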