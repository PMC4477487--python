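import numpy as np
import pytest

from fibrilscatter.simulate import GroundTruth


@pytest.fixture
def bamboo_truth():
    """Default bamboo-like ground truth, 1% relative noise."""
    return GroundTruth.bamboo(seed=0)


@pytest.fixture
def noiseless_truth():
    return GroundTruth.bamboo(seed=0, noise_fraction=0.0)


@pytest.fixture
def simple_profile():
    """Minimal well-formed radial profile."""
    from fibrilscatter.profiles import RadialProfile

    q = np.array([1.0, 2.0, 3.0, 4.0])
    return RadialProfile(q, q**2, meta={"radiation": "neutron", "wavelength_nm": 0.242})
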