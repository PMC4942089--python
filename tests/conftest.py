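import numpy as np
import pytest

from matesim import (
    Grid,
    extract_membrane_curve,
    init_circle_levelset,
)

#: Batch operating resolution (see docs/methods.md): coarser than the
#: reference mesh but with the same physics; keeps full simulations at a few
#: seconds each.
FAST = dict(h=0.08, n_markers=200, field_update_interval=5)

NOISE_FREE = dict(kappa1=0.0, kappa2=0.0, kappa3=0.0)


@pytest.fixture(scope="session")
def grid08():
    return Grid(-3.6, 3.6, -1.6, 1.6, 0.08)


@pytest.fixture(scope="session")
def circle_ls(grid08):
    return init_circle_levelset((-2.0, 0.0), 1.0, grid08, "a0")


@pytest.fixture(scope="session")
def circle_curve(grid08, circle_ls):
    return extract_membrane_curve(circle_ls, 200, center0=np.array([-2.0, 0.0]))


@pytest.fixture(scope="session")
def circle_theta(circle_curve):
    p = circle_curve.points
    return np.arctan2(p[:, 1], p[:, 0] + 2.0)
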