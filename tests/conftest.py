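import pytest

from cogbn.discretize import DiscretizationMap, apply_discretization
from cogbn.synth import default_ground_truth, random_model, sample_cohort


@pytest.fixture(scope="session")
def gt_config():
    return default_ground_truth()


@pytest.fixture(scope="session")
def planted_map(gt_config):
    return DiscretizationMap.from_variable_specs(gt_config.variables)


@pytest.fixture(scope="session")
def cohort(gt_config):
    """A medium synthetic cohort with the default 5% missingness."""
    return sample_cohort(gt_config, 1500, seed=11)


@pytest.fixture(scope="session")
def planted_data(gt_config, planted_map, cohort):
    return apply_discretization(cohort, planted_map)


@pytest.fixture(scope="session")
def planted_model(gt_config):
    return gt_config.model()


@pytest.fixture
def random_model_factory():
    return random_model
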