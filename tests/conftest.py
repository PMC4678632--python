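import numpy as np
import pytest

from stratiquant import LayerBoundarySet, validate_boundaries
from stratiquant import synthetic as syn


def straight_boundary_set(rows=(300.0, 240.0, 140.0, 110.0), frame_shape=(768, 256)):
    """Four straight horizontal boundaries at the given rows (deep→surface)."""
    H, W = frame_shape
    polys = [np.array([[0.0, r], [W - 1.0, r]]) for r in rows]
    return validate_boundaries(LayerBoundarySet(polys, frame_shape=frame_shape))


@pytest.fixture
def straight_boundaries():
    return straight_boundary_set()


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-frame tissue spec used across tests (same physics as default)."""
    return syn.SyntheticTissueSpec(frame_width_px=256, frame_height_px=768)


@pytest.fixture(scope="session")
def small_sim(small_spec):
    """One generated synthetic acquisition shared by read-only tests."""
    stack, truth = syn.generate_stack(small_spec, seed=7)
    return stack, truth
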