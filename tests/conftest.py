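import numpy as np
import pytest

from cestpipe import AcquisitionConfig
from cestpipe.zspec import LorentzianPeak


@pytest.fixture(scope="session")
def offsets():
    """Default saturation grid: -6..6 ppm at 0.12 ppm (101 samples)."""
    return AcquisitionConfig().offsets


@pytest.fixture(scope="session")
def five_pool_truth():
    """Nominal five-pool truth used for round-trip experiments."""
    return [
        LorentzianPeak("water", 0.0, 0.80, 2.0),
        LorentzianPeak("hydroxyl", 1.2, 0.03, 1.0),
        LorentzianPeak("amine", 2.4, 0.04, 1.2),
        LorentzianPeak("amide", 3.5, 0.05, 1.0),
        LorentzianPeak("noe_mt", -3.0, 0.10, 5.0),
    ]


@pytest.fixture()
def small_config():
    """Small noiseless acquisition for fast phantom tests."""
    return AcquisitionConfig(grid_size=12, noise_sigma=0.0, seed=7)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (draws never depend on test order)."""
    return np.random.default_rng(20240901)
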