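import numpy as np
import pytest

from spectraldcm.config import load_defaults
from spectraldcm.neural_mass import (
    FrequencyGrid,
    SourceParams,
    single_source_model,
    transfer_csd,
)


@pytest.fixture(scope="session")
def config():
    return load_defaults()


@pytest.fixture(scope="session")
def grid():
    """Default empirical fitting grid."""
    return FrequencyGrid.regular(0.25, 10.0, 0.25)


@pytest.fixture(scope="session")
def base_model():
    return single_source_model()


@pytest.fixture(scope="session")
def base_csd(base_model, grid):
    return transfer_csd(base_model, grid)


@pytest.fixture(scope="session")
def fig1_segments():
    """One fixed-seed construct-validity segment set, reused across tests."""
    from spectraldcm.synthetic_data import generate_fig1_segments

    return generate_fig1_segments(seed=1)


def make_source(**kwargs) -> SourceParams:
    h = np.zeros(5)
    for k in list(kwargs):
        if k.startswith("h") and k[1:].isdigit():
            h[int(k[1:]) - 1] = kwargs.pop(k)
    return SourceParams(h=h, **kwargs)
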