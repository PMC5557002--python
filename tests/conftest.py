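import numpy as np
import pytest

from phyloniche.geodata import RasterLayer, RasterStack
from phyloniche.trees import Chronogram


@pytest.fixture
def small_layer():
    """3x3 grid over lon [100, 103), lat [0, 3), one nodata cell."""
    values = np.array([
        [1.0, 2.0, 3.0],
        [4.0, -9999.0, 6.0],
        [7.0, 8.0, 9.0],
    ])
    return RasterLayer("Bio1", values, (100.0, 103.0, 0.0, 3.0), 1.0, -9999.0)


@pytest.fixture
def constant_stack():
    """Two constant layers (7 and 3) on the small grid."""
    ext = (100.0, 103.0, 0.0, 3.0)
    return RasterStack([
        RasterLayer("Bio1", np.full((3, 3), 7.0), ext, 1.0),
        RasterLayer("Bio12", np.full((3, 3), 3.0), ext, 1.0),
    ])


@pytest.fixture
def cherry_tree():
    return Chronogram.from_newick("(x:1.0,y:1.0);")


@pytest.fixture
def star3_tree():
    """Three tips radiating from a near-root node: ((a,b),c) with a tiny
    internal edge approximating a star for the parsimony closed form."""
    return Chronogram.from_newick("(a:1.0,b:1.0,c:1.0);")


@pytest.fixture
def balanced4_tree():
    return Chronogram.from_newick("((a:1.0,b:1.0):1.0,(c:1.5,d:1.5):0.5);")
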