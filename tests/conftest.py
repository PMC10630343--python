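import numpy as np
import pytest

from marshnet import GridSpec, ModelParams


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(n_x=12, n_y=16, dx=0.5, dy=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def closed_box_state(grid: GridSpec, rng: np.random.Generator,
                     h0: float = 0.02, u_scale: float = 0.01):
    """Random smooth state whose boundary values satisfy reflecting
    (closed) conditions on *all four* sides, including the normally open
    outflow side, so discrete flux divergences telescope to zero."""
    shape = grid.shape
    h = h0 + 0.002 * rng.standard_normal(shape)
    u = u_scale * rng.standard_normal(shape)
    v = u_scale * rng.standard_normal(shape)
    for f in (h,):
        f[0, :] = f[1, :]
        f[-1, :] = f[-2, :]
        f[:, 0] = f[:, 1]
        f[:, -1] = f[:, -2]
    u[0, :] = -u[1, :]
    u[-1, :] = -u[-2, :]
    u[:, 0] = u[:, 1]
    u[:, -1] = u[:, -2]
    v[0, :] = v[1, :]
    v[-1, :] = v[-2, :]
    v[:, 0] = -v[:, 1]
    v[:, -1] = -v[:, -2]
    return h, u, v
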