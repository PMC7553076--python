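import numpy as np
import pytest
from hypothesis import settings

from wienerfit import DMParams, Dataset, sample_trials

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def theta_unbiased():
    """Unbiased reference parameter set used across modules."""
    return DMParams(a=1.0, z_rel=0.5, ter=0.3, v=0.5)


@pytest.fixture(scope="session")
def data_400(theta_unbiased):
    """A well-behaved n=400 dataset at the unbiased reference truth."""
    return sample_trials(theta_unbiased, 400, seed=42)


@pytest.fixture(scope="session")
def data_100(theta_unbiased):
    return sample_trials(theta_unbiased, 100, seed=7)


@pytest.fixture()
def toy_dataset():
    """Tiny handmade dataset: 3 upper (0.5, 0.7, 0.9 s), 1 lower (0.6 s)."""
    return Dataset(responses=np.array([1, 1, 1, 0]),
                   rts=np.array([0.5, 0.7, 0.9, 0.6]))


# a small but varied slice of the study's parameter grid
GRID_SLICE = [
    DMParams(0.5, 0.5, 0.1, 0.0),
    DMParams(1.0, 0.2, 0.3, 1.0),
    DMParams(1.0, 0.8, 0.5, -0.5),
    DMParams(1.5, 0.5, 0.3, 0.5),
    DMParams(2.0, 0.2, 0.1, -1.0),
    DMParams(2.0, 0.8, 0.5, 1.0),
]


@pytest.fixture(params=GRID_SLICE, ids=lambda p: f"a{p.a}-z{p.z_rel}-v{p.v}")
def grid_params(request):
    return request.param
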