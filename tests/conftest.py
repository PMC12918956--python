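import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from epijam.synthetic import (MonolayerConfig, generate_fluid,
                              generate_rigid_pack)


@pytest.fixture(scope="session")
def rigid_run():
    """Small rigid-pack movie with scripted interface T1 events."""
    cfg = MonolayerConfig(n_cells=100, box_size=250.0, mode="rigid_pack",
                          pack_size=80.0, speed=10.0, interface_t1_rate=0.04,
                          n_frames=81, noise_sigma=0.0, seed=7)
    return generate_rigid_pack(cfg)


@pytest.fixture(scope="session")
def fluid_run():
    """Small fluid movie with distributed scripted T1 events."""
    cfg = MonolayerConfig(n_cells=100, box_size=250.0, mode="fluid",
                          speed=10.0, fluid_t1_gain=0.003, n_frames=81,
                          seed=11)
    return generate_fluid(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
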