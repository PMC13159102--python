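import numpy as np
import pytest

from centroclust.sim import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_config():
    """Smallest config that exercises every entity type, fast to run."""
    return SimConfig(
        arena_radius=5.0,
        dt=0.01,
        t_bundle=2.0,
        t_total=6.0,
        snapshot_interval=2.0,
        n_filaments=4,
        filament_length=4.0,
        filament_segment_length=2.0,
        n_hset=10,
        hset_binding_range=0.1,
        hset_link_stiffness=40.0,
        n_complexes=8,
        complex_adhesive_stiffness=20.0,
        complex_adhesive_range=0.1,
        seed=7,
    )


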