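import numpy as np
import pytest

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass

from xeosc import SequenceParams, simulate_acquisition
from xeosc.phantom import make_phantom, two_ellipsoid_lungs
from xeosc.pipeline import ReconContext


@pytest.fixture(scope="session")
def small_seq():
    """Desk-scale sequence: 300 spokes, 16^3 matrix, same timing as default."""
    return SequenceParams(n_spokes=300, recon_matrix=16, nominal_matrix=10)


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(grid=16, alpha_default=0.20, heart_rate=70.0)


@pytest.fixture(scope="session")
def small_acq(small_phantom, small_seq):
    return simulate_acquisition(small_phantom, small_seq, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_ctx(small_acq):
    return ReconContext.for_acquisition(small_acq)
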