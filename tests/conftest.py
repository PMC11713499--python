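import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sctqa import (
    BeamSpec,
    BinaryMask,
    ErrorModel,
    PhantomSpec,
    ScalarVolume,
    generate_case,
)


@pytest.fixture
def unit_volume():
    """A tiny 4x4x4 volume with 1 mm spacing and origin at zero."""
    values = np.arange(64, dtype=float).reshape(4, 4, 4)
    return ScalarVolume(values, spacing=(1, 1, 1), origin=(0, 0, 0))


@pytest.fixture
def small_spec():
    """Coarse phantom spec sized for fast unit tests."""
    return PhantomSpec(grid_shape=(32, 36, 32), spacing=(5.0, 5.0, 5.0),
                       seed=7)


@pytest.fixture
def identity_case(small_spec):
    """Phantom case with an all-zero error model: sCT == pCT."""
    return generate_case(small_spec, ErrorModel(), BeamSpec(), case_id="ident")


@pytest.fixture
def bias_case(small_spec):
    """Phantom case whose only conversion error is a +25 HU bias."""
    return generate_case(small_spec, ErrorModel(global_bias=25.0), BeamSpec(),
                         case_id="bias25")


def full_mask(volume: ScalarVolume, name: str = "ALL") -> BinaryMask:
    return BinaryMask(name, np.ones(volume.shape, dtype=bool),
                      volume.spacing, volume.origin)
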