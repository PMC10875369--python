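import numpy as np
import pytest

from nbpfweibull import NBPFParams, nbpf_rvs


@pytest.fixture(scope="session")
def standard_params():
    """The three true-parameter triples used throughout the estimator study."""
    return [
        NBPFParams(1.7, 0.9, 1.5),
        NBPFParams(1.5, 0.6, 1.1),
        NBPFParams(1.9, 0.4, 1.7),
    ]


@pytest.fixture(scope="session")
def medium_sample():
    """One fixed 300-observation sample from the first standard triple."""
    return nbpf_rvs(300, NBPFParams(1.7, 0.9, 1.5), seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(20240206)
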