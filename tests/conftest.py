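"""Shared fixtures: models, profile database, fixture sets, simulations.

Expensive artifacts (calibrated profile database, classifier fixture
calls, scenario simulations) are session-scoped so the acceptance tests
and unit tests share one computation.
"""

import numpy as np
import pytest

from lhc_origins.evolve_models import RateModel
from lhc_origins.family_classifier import classify_batch
from lhc_origins.synthetic_data import (ScenarioConfig,
                                        make_classifier_fixtures,
                                        make_profile_db, make_reference_set,
                                        simulate_scenario)


@pytest.fixture(scope="session")
def dayhoff():
    return RateModel("dayhoff", alpha=1.0, k=4)


@pytest.fixture(scope="session")
def wag():
    return RateModel("wag", alpha=1.0, k=4)


@pytest.fixture(scope="session")
def profile_db():
    return make_profile_db(seed=0, n_random=2000)


@pytest.fixture(scope="session")
def reference_set():
    return make_reference_set()


@pytest.fixture(scope="session")
def classifier_fixture_set():
    records, truth = make_classifier_fixtures(n_records=500, seed=0)
    return records, truth


@pytest.fixture(scope="session")
def classifier_calls(profile_db, reference_set, classifier_fixture_set):
    records, truth = classifier_fixture_set
    calls, summary = classify_batch(records, profile_db, reference_set)
    return calls, summary, truth


@pytest.fixture(scope="session")
def independent_sim():
    return simulate_scenario(ScenarioConfig(scenario="independent", seed=1))


@pytest.fixture(scope="session")
def common_sim():
    return simulate_scenario(ScenarioConfig(scenario="common", seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
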