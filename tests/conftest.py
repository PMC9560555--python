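import numpy as np
import pytest

from qifex.params import MeanFieldParams


@pytest.fixture(scope="session")
def mpr_params() -> MeanFieldParams:
    """The standard folded-manifold parameter set (Delta=1, J=15)."""
    return MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=0.002)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
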