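import numpy as np
import pytest

from thoravol import LabelMask, VoxelSpacing
from thoravol.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def unit_spacing():
    return VoxelSpacing(1.0, 1.0, 1.0)


@pytest.fixture
def mask_factory(unit_spacing):
    """Build a LabelMask from an array (unit spacing unless overridden)."""

    def make(arr, spacing=None):
        return LabelMask(np.asarray(arr, dtype=np.int16), spacing or unit_spacing)

    return make


@pytest.fixture(scope="session")
def default_phantom():
    """One default 3-lesion phantom, shared across read-only tests."""
    return generate_phantom(PhantomSpec(seed=42))
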