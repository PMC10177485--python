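import numpy as np
import pytest

from verdictbrain.scheme import AcquisitionScheme, build_reference_protocol


@pytest.fixture(scope="session")
def protocol():
    """The built-in 12-shell multi-TE protocol (cached, read-only)."""
    return build_reference_protocol()


@pytest.fixture(scope="session")
def weighted(protocol):
    """Protocol restricted to weighted records (attenuation domain)."""
    return protocol.subset(np.nonzero(protocol.weighted)[0])


def single_measurement_scheme(b, delta_ms, Delta_ms, direction=(1.0, 0.0, 0.0)):
    """One weighted measurement plus its b=0 anchor."""
    return AcquisitionScheme(
        b=np.array([b, 0.0]),
        directions=np.array([list(direction), [0.0, 0.0, 0.0]]),
        delta=np.array([delta_ms] * 2),
        Delta=np.array([Delta_ms] * 2),
        te=np.array([80.0] * 2),
        shell=np.array([0, -1]),
    )


@pytest.fixture
def one_shot():
    return single_measurement_scheme
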