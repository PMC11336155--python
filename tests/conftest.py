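import numpy as np
import pytest

from dermakin import FiberPhantomSpec, generate_fiber_volume, collagen_mask


@pytest.fixture(scope="session")
def aligned_phantom():
    """Small phantom with every fiber along +x (degenerate concentration)."""
    spec = FiberPhantomSpec(
        shape=(64, 64, 48), n_fibers=40, mean_axis=(1, 0, 0),
        concentration=np.inf, noise_sd=0.0, seed=3,
    )
    shg, tpef, truth = generate_fiber_volume(spec)
    return spec, shg, tpef, truth


@pytest.fixture(scope="session")
def sparse_phantom():
    """Moderate-density phantom with known per-voxel axes (kappa = 8)."""
    spec = FiberPhantomSpec(
        shape=(96, 96, 48), n_fibers=60, fiber_radius=2.0,
        concentration=8.0, noise_sd=0.0, seed=7,
    )
    shg, tpef, truth = generate_fiber_volume(spec)
    return spec, shg, tpef, truth


@pytest.fixture(scope="session")
def aligned_mask(aligned_phantom):
    _, shg, _, _ = aligned_phantom
    return collagen_mask(shg)
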