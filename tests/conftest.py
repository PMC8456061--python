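import numpy as np
import pytest

from sonaxon import BLSConstants, build_lookup, get_membrane


@pytest.fixture(scope="session")
def consts():
    return BLSConstants()


@pytest.fixture(scope="session")
def fh():
    return get_membrane("senn_node")


@pytest.fixture(scope="session")
def sundt():
    return get_membrane("sundt")


@pytest.fixture(scope="session")
def fh_lookup(fh):
    """Small effective-variable table for the Ranvier-node membrane."""
    A = np.array([0.0, 30e3, 60e3, 100e3, 150e3])
    Q = np.linspace(fh.Cm0 * -0.1, fh.Cm0 * 0.05, 20)
    return build_lookup(fh, A_grid=A, Q_grid=Q, fs=0.8)
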