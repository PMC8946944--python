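import numpy as np
import pytest

from pimoquant import synth
from pimoquant.types import BinaryMask, ChannelImage


@pytest.fixture
def noiseless_spec():
    """Noiseless default section: every recovery check is exact."""
    return synth.SectionSpec(noise_sd=0.0, seed=11)


@pytest.fixture
def noiseless_section(noiseless_spec):
    return synth.generate_section(noiseless_spec)


def disk_mask(shape, center, radius_px):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


@pytest.fixture
def disk_factory():
    return disk_mask


def channel(pixels, px_um=1.0, label="img"):
    return ChannelImage(np.asarray(pixels, dtype=float), px_um, label=label)


def mask(pixels, px_um=1.0):
    return BinaryMask(np.asarray(pixels, dtype=bool), px_um)
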