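import numpy as np
import pytest

from uptakealloc import CellParameters, TransportParameters


@pytest.fixture(scope="session")
def baseline():
    return TransportParameters.baseline()


@pytest.fixture(scope="session")
def cell():
    return CellParameters()


def random_transport_params(rng: np.random.Generator) -> TransportParameters:
    """Log-uniform draw over +/-2 decades around the baseline rate set."""
    b = TransportParameters.baseline()
    draw = lambda v: v * 10.0 ** rng.uniform(-2, 2)
    return TransportParameters(
        k1=draw(b.k1), k2=draw(b.k2), k0f=draw(b.k0f), k0r=draw(b.k0r),
        k1p=draw(b.k1p), k2p=draw(b.k2p), k3p=draw(b.k3p),
    )
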