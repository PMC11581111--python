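import numpy as np
import pytest

import voxmap as vm
from voxmap import phantom as ph


@pytest.fixture(scope="session")
def small_atlas():
    """4 parents x 3 children toy atlas on a 48x40x32 grid, 10 um voxels."""
    return vm.build_toy_atlas((48, 40, 32), n_parents=4, children_per_parent=3, seed=11)


@pytest.fixture(scope="session")
def bench_atlas():
    """Benchmark-scale atlas (96x80x64, 12 leaves)."""
    return vm.build_toy_atlas((96, 80, 64), n_parents=4, children_per_parent=3, seed=11)


@pytest.fixture
def aggregate_cfg():
    """Single aggregate-channel phantom config on the small grid."""

    def make(effects=(), n_per_group=4, master_seed=5, noise_sd=5.0, artifact=None):
        return ph.PhantomConfig(
            grid_shape=(48, 40, 32),
            n_per_group=n_per_group,
            master_seed=master_seed,
            channels=[ph.ChannelSpec("abeta", "aggregate", 100.0, 2000.0, 20.0)],
            effects=list(effects),
            noise_sd=noise_sd,
            artifact=artifact if artifact is not None else ph.ArtifactSpec(),
        )

    return make


@pytest.fixture
def ramp_volume():
    vals = np.arange(8 * 8 * 8, dtype=np.float32).reshape(8, 8, 8)
    return vm.Volume3D(vals, (10.0, 10.0, 10.0))
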