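import numpy as np
import pytest

from canopysphere import AnnulusSet, LensFunction, Panorama, SlabCanopy


@pytest.fixture
def linear_lens():
    return LensFunction()


@pytest.fixture
def five_annuli():
    return AnnulusSet()


@pytest.fixture
def uniform_slab():
    """1 m² m⁻³ from ground to 6 m, spherical leaf angles."""
    return SlabCanopy(layers=[(0.0, 6.0, 1.0)])


@pytest.fixture
def split_pano():
    """Upper hemisphere bright (255), lower dark (0)."""
    px = np.zeros((100, 200))
    px[:50] = 255.0
    return Panorama(pixels=px)
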