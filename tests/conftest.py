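import numpy as np
import pytest

from abcells.geometry import Polygon


@pytest.fixture
def unit_square() -> Polygon:
    return Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def ellipse_2_1() -> Polygon:
    """64-gon approximation of the axis-aligned ellipse a=2, b=1."""
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    return Polygon(np.c_[2 * np.cos(t), np.sin(t)])


@pytest.fixture
def circle_64() -> Polygon:
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    return Polygon(np.c_[np.cos(t), np.sin(t)])
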