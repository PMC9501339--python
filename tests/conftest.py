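import numpy as np
import pytest

from biofilmorph import BinaryGrid


@pytest.fixture
def random_mask_factory():
    """Seeded random calibrated masks for oracle cross-checks."""

    def make(seed: int, shape=(16, 16, 16), p=0.3, dx=0.5, dy=0.4, dz=1.0) -> BinaryGrid:
        rng = np.random.default_rng(seed)
        return BinaryGrid(mask=rng.random(shape) < p, dx=dx, dy=dy, dz=dz)

    return make


@pytest.fixture
def slab_mask():
    """A uniform 10-slice slab covering the full field, dz=1 (h ≡ 10 μm)."""
    return BinaryGrid(mask=np.ones((10, 8, 8), dtype=bool), dx=1.0, dy=1.0, dz=1.0)
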