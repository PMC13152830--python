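import numpy as np
import pytest

from lcskit.lcs_models import build_bivariate_lcs, theta_from_labels
from lcskit.sem_core import SampleMoments, compile_model, implied_moments
from lcskit.synthetic_data import recovery_parameters, table1_fixture

FF = [f"FF_T{t}" for t in range(1, 5)]
EP = [f"EP_T{t}" for t in range(1, 5)]


@pytest.fixture(scope="session")
def bivariate_model():
    return compile_model(build_bivariate_lcs(4))


@pytest.fixture(scope="session")
def theta_star(bivariate_model):
    return theta_from_labels(bivariate_model, recovery_parameters().label_values())


@pytest.fixture(scope="session")
def exact_moments(bivariate_model, theta_star):
    """Moments generated exactly by the model at theta*."""
    mu, Sigma = implied_moments(bivariate_model, theta_star)
    return SampleMoments(bivariate_model.observed_names, mu, Sigma, 468)


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()
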