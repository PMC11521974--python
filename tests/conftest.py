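import numpy as np
import pytest

from otokit import synthetic as syn


@pytest.fixture(scope="session")
def sled_13g():
    """High-level (1.3 G) sled trace shared by LVOR tests."""
    return syn.gen_sled_trace(syn.SledParams.level_1_3g())


@pytest.fixture(scope="session")
def default_phantom():
    """Default (plain-ellipsoid) phantom with ROIs and ground truth."""
    return syn.gen_ct_phantom(syn.PhantomParams(seed=0))


def random_volume(rng, max_side=16):
    """Small random CT volume + ROI used by oracle-equivalence tests."""
    from otokit.types import CTVolume, VolumeMeta

    shape = tuple(rng.integers(4, max_side + 1, size=3))
    vox = rng.normal(100.0, 40.0, size=shape)
    roi = rng.random(shape) < 0.6
    roi.flat[0] = True  # never empty
    vol = CTVolume(vox, VolumeMeta(spacing_um=(5.0, 5.0, 5.0)))
    return vol, roi
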