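import numpy as np
import pytest

from nucleoquant import synthetic as syn
from nucleoquant.afm import HeightMap


@pytest.fixture()
def flat_map():
    """512 x 512 flat background at 0 nm, 1 nm/pixel."""
    return HeightMap(grid=np.zeros((512, 512)), rx=1.0, ry=1.0)


@pytest.fixture()
def noiseless_render():
    """RenderParams with noise off for integral/bookkeeping checks."""
    return syn.RenderParams(extent=(128, 128), noise_sigma=0.0)


@pytest.fixture()
def small_scene():
    """One rendered multi-chain scene with particles and its manifest."""
    return syn.simulate_afm_scene(n_chains=4, seed=42)


def make_rod_mask(length=60, width=3, pad=10):
    """Horizontal rod mask, full-image bool array."""
    ny = width + 2 * pad
    nx = length + 2 * pad
    mask = np.zeros((ny, nx), dtype=bool)
    mask[pad : pad + width, pad : pad + length] = True
    return mask
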