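import numpy as np
import pytest

from edemaquant import CTVolume, LungMask


@pytest.fixture
def unit_volume():
    """8x8x8 all-air volume at 1 mm isotropic spacing."""
    return CTVolume(data=np.full((8, 8, 8), -1000.0), affine=np.eye(4))


@pytest.fixture
def full_mask():
    return LungMask(data=np.ones((8, 8, 8), dtype=bool), affine=np.eye(4))


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    affine = np.diag(list(spacing) + [1.0])
    return CTVolume(data=np.asarray(values, dtype=float), affine=affine)


def make_mask(values, spacing=(1.0, 1.0, 1.0)):
    affine = np.diag(list(spacing) + [1.0])
    return LungMask(data=np.asarray(values) > 0, affine=affine)
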