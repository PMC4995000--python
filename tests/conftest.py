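"""Shared fixtures.

The expensive fitting experiments (noiseless parameter recovery and the
ten-seed noisy acceptance batch) run once per session and are shared
between the unit tests and the acceptance suite.
"""

import numpy as np
import pytest

from tcommit.calibration import derive_notch_bounds, filter_fits, fit_tgb, series_map
from tcommit.estimation import CommitmentModel
from tcommit.params import demo_spec, winning_spec, WINNING_VARIANTS
from tcommit.staging import smooth_series
from tcommit.synthetic import generate_reference_dataset


@pytest.fixture(scope="session")
def reference_spec():
    return demo_spec()


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate_reference_dataset(seed=3, noise_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_profiles(noiseless_dataset):
    return {g: smooth_series(s)
            for g, s in series_map(noiseless_dataset.series).items()}


@pytest.fixture(scope="session")
def noiseless_bounds(noiseless_dataset, noiseless_profiles):
    return derive_notch_bounds(
        noiseless_profiles, noiseless_dataset.truth.logic, seed=0
    )


@pytest.fixture(scope="session")
def noiseless_fits(noiseless_dataset, noiseless_bounds):
    """Recovery experiment: refit the generating configuration, 5 seeds."""
    fits = []
    for seed in range(1, 6):
        fit = fit_tgb(
            noiseless_dataset.truth.logic, noiseless_dataset.series,
            noiseless_bounds, seed=seed, maxiter=100,
        )
        filter_fits([fit], noiseless_dataset.series)
        fits.append(fit)
    return fits


@pytest.fixture(scope="session")
def noisy_fit_batch():
    """Ten seeded end-to-end fits of the generating configuration at CV 25%."""
    results = []
    for seed in range(1, 11):
        ds = generate_reference_dataset(seed=seed, noise_cv=0.25)
        model = CommitmentModel(ds.series, logic="6d")
        results.append(model.fit(seed=seed, maxiter=80))
    return results


@pytest.fixture(scope="session")
def winning_specs():
    return {vid: winning_spec(vid) for vid in WINNING_VARIANTS}
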