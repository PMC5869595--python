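import numpy as np
import pytest

from srsmotor.params import ModelParams
from srsmotor.substrate import SubstrateSpec


@pytest.fixture
def tiny_spec() -> SubstrateSpec:
    """50-site lattice with a 4-site SRS block, oracle-sized."""
    return SubstrateSpec(length_bp=50,
                         srs_intervals=((10, 14, "toward_left_end"),))


@pytest.fixture
def tiny_params() -> ModelParams:
    """Fast-mixing no-ATP parameters for tiny-lattice cross-checks."""
    return ModelParams(p_on_srs=0.1, p_on_ns=0.1, p_off_srs=0.02,
                       p_off_ns=0.05, sld_ns_mean=8.0, sld_ns_sd=2.0,
                       equilibration_mcs=800, sampling_mcs=2000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
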