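"""Shared fixtures: one medium synthetic bundle and fitted models, reused
across test modules to keep the suite fast."""

import pytest

from pregsae import GroundTruth, generate_bundle
from pregsae.models import fit_intendedness_model, fit_livebirth_model

FAST_GRID = [{"family": "logistic", "params": {"C": 1.0}}]
SMALL_GRID = [
    {"family": "logistic", "params": {"C": 1.0}},
    {"family": "random_forest", "params": {"n_estimators": 100, "min_samples_leaf": 20}},
]


@pytest.fixture(scope="session")
def small_truth():
    return GroundTruth(
        seed=11,
        area_count=5,
        births_per_area=600,
        women_per_area=(2000, 4000),
    )


@pytest.fixture(scope="session")
def small_bundle(small_truth):
    return generate_bundle(small_truth, sampling_rate=0.3, weight_dispersion=0.3, n_women=2500)


@pytest.fixture(scope="session")
def fitted_f(small_bundle):
    return fit_intendedness_model(
        small_bundle.survey_table, k_folds=3, seed=11, candidate_grid=SMALL_GRID
    )


@pytest.fixture(scope="session")
def fitted_g(small_bundle):
    return fit_livebirth_model(
        small_bundle.pregnancy_table, k_folds=3, seed=11, candidate_grid=FAST_GRID
    )
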