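import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phenorec import (
    CohortConfig,
    default_decision_tree,
    generate_cohort,
    simulate_sessions,
    build_feature_table,
    SoftL1KMeans,
)
from phenorec.cohort import cohort_frame

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def default_events(default_cohort, default_config):
    tree = default_decision_tree(default_config.n_exercises)
    return simulate_sessions(default_cohort, tree, default_config, seed=1)


@pytest.fixture(scope="session")
def default_table(default_cohort, default_events):
    return build_feature_table(cohort_frame(default_cohort), default_events)


@pytest.fixture(scope="session")
def default_model(default_table):
    return SoftL1KMeans(
        n_clusters=4, feature_weights=default_table.weights, n_init=10, random_state=0
    ).fit(default_table.values)


@pytest.fixture(scope="session")
def planted_labels(default_cohort):
    return np.array([r.latent_profile for r in default_cohort])
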