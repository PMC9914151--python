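import numpy as np
import pytest

import effimarkov as em


@pytest.fixture(scope="session")
def study_panel() -> em.EfficiencyPanel:
    return em.datasets.load_efficiency_panel()


@pytest.fixture(scope="session")
def contiguity() -> em.AdjacencyMap:
    return em.datasets.load_contiguity()


@pytest.fixture(scope="session")
def study_breaks(study_panel):
    return em.fit_state_breaks(study_panel, k=4, pool="per_year")


@pytest.fixture(scope="session")
def study_states(study_panel, study_breaks) -> em.StatePanel:
    return em.classify_states(study_panel, study_breaks)


@pytest.fixture(scope="session")
def study_spatial(study_panel, study_states, study_breaks, contiguity):
    lag = em.spatial_lag_states(study_panel, contiguity, study_breaks)
    return em.spatial_transition_set(study_states, lag)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
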