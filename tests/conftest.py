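import numpy as np
import pytest

from seldi_nodal.spectra_io import NODE_NEGATIVE, NODE_POSITIVE
from seldi_nodal.synthetic_data import (
    GeneratorConfig,
    PeakSpec,
    default_generator_config,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return default_generator_config()


@pytest.fixture
def mini_config():
    """Small-grid generator config (3 peaks, 2 kDa span) for fast tests."""
    peaks = [
        PeakSpec(2500.0, 4.0, 0.5, 2.0, 0.4, differential=True),
        PeakSpec(3000.0, 1.5, 0.2, 1.5, 0.2, differential=False),
        PeakSpec(3600.0, 8.0, 1.0, 5.0, 0.8, differential=True),
    ]
    cfg = GeneratorConfig(peaks=peaks, grid_min=2000.0, grid_max=4000.0,
                          grid_step=1.0, baseline_amplitude=5.0,
                          baseline_decay=1500.0, noise_sd=0.05)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def table1_mean_vectors():
    """Feature-name -> class-mean maps for the 22 differential peaks."""
    from seldi_nodal.synthetic_data import table1_params

    pos = {f"mz_{int(p.mz_center)}": p.mean_pos for p in table1_params()}
    neg = {f"mz_{int(p.mz_center)}": p.mean_neg for p in table1_params()}
    return pos, neg


POS = NODE_POSITIVE
NEG = NODE_NEGATIVE
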