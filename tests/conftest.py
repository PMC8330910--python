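import numpy as np
import pytest

from mitoros.phantom import Phantom, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom0() -> Phantom:
    """Default 0.25-um phantom, shared across tests (deterministic)."""
    return generate_phantom(seed=0)


@pytest.fixture(scope="session")
def coarse_phantom() -> Phantom:
    """1-um-voxel phantom for cheap PDE invariant checks."""
    return generate_phantom(PhantomConfig(voxel_um=1.0), seed=0)


def make_empty_phantom(domain, voxel) -> Phantom:
    """A phantom with no bodies (all interstitial fluid), synthetic helper."""
    cfg = PhantomConfig(domain_um=domain, voxel_um=voxel)
    shape = tuple(int(round(d / voxel)) for d in domain)
    labels = np.zeros(shape, dtype=np.uint8)
    origin = -np.asarray(domain) / 2.0
    return Phantom(cfg, [], labels, voxel, origin)
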