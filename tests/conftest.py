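import numpy as np
import pytest

from fractomics import ImageVolume, PhantomSpec, RoiMask, simulate_tumor_volume


@pytest.fixture(scope="session")
def phantom():
    """Default tumor phantom: (volume, mask) with mid-level heterogeneity."""
    return simulate_tumor_volume(PhantomSpec(seed=7))


@pytest.fixture
def small_volume():
    """Deterministic 4-slice 16x16 volume with a centered box ROI."""
    rng = np.random.default_rng(42)
    voxels = rng.normal(100.0, 10.0, size=(4, 16, 16))
    vol = ImageVolume(voxels=voxels, spacing_mm=(3.0, 0.8, 0.8))
    m = np.zeros((4, 16, 16), dtype=bool)
    m[:, 4:12, 4:12] = True
    mask = RoiMask(voxels=m, spacing_mm=vol.spacing_mm)
    return vol, mask
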