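import numpy as np
import pytest

from segrefine.phantom import PhantomSpec, generate_phantom, perturb_mask, resolve_spec


@pytest.fixture(scope="session")
def phantom0():
    """Default phantom, seed 0: (resolved spec, volume, gt mask)."""
    spec = resolve_spec(PhantomSpec(seed=0))
    vol, gt = generate_phantom(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def phantom0_slice(phantom0):
    """The axial slice of phantom 0 with the largest liver cross-section."""
    _, vol, gt = phantom0
    k = int(gt.data.sum(axis=(0, 1)).argmax())
    return vol.data[:, :, k], gt.data[:, :, k]


@pytest.fixture(scope="session")
def eroded_init0(phantom0):
    _, _, gt = phantom0
    return perturb_mask(gt, "erode_boundary", 2, seed=0)


def random_mask_pair(rng, shape):
    """A random pair of non-degenerate binary masks for metric tests."""
    a = (rng.random(shape) < 0.35).astype(np.uint8)
    b = (rng.random(shape) < 0.35).astype(np.uint8)
    return a, b
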