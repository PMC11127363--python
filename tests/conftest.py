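import numpy as np
import pytest

from phrflow.flow.core import ConditionalFlow, FlowConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def randomize_flow(flow: ConditionalFlow, rng: np.random.Generator,
                   scale: float = 0.3) -> ConditionalFlow:
    """Fill every parameter with random values so layers are non-trivial
    (fresh flows are exact identities by construction).  Weight matrices
    are scaled by 1/sqrt(fan-in), as trained networks are, so the map
    stays numerically well conditioned at any width."""
    for _, p, _ in flow.named_parameters(include_base=True):
        if p.ndim == 2:
            p[...] = rng.normal(0.0, scale / np.sqrt(p.shape[0]), p.shape)
        else:
            p[...] = rng.normal(0.0, 0.3 * scale, p.shape)
    return flow


@pytest.fixture
def small_flow(rng):
    """A non-trivial randomized flow at d = 6."""
    flow = ConditionalFlow(FlowConfig(d=6, d_c=2, n_blocks=3,
                                      hidden_width=16, seed=1))
    return randomize_flow(flow, rng)


def density_integral_2d(flow, c_row, n_grid: int = 450) -> float:
    """Quadrature of exp(log_likelihood) over a grid sized from the flow's
    own samples, so the support is covered whatever the layer scales are."""
    r = np.random.default_rng(0)
    samples = flow.sample(np.tile(c_row, (4000, 1)), r)
    lo = samples.min(axis=0) - 3.0 * samples.std(axis=0)
    hi = samples.max(axis=0) + 3.0 * samples.std(axis=0)
    gx = np.linspace(lo[0], hi[0], n_grid)
    gy = np.linspace(lo[1], hi[1], n_grid)
    xx, yy = np.meshgrid(gx, gy)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    c = np.tile(c_row, (len(pts), 1))
    p = np.exp(flow.log_likelihood(pts, c))
    return float(p.sum() * (gx[1] - gx[0]) * (gy[1] - gy[0]))


def numerical_jacobian(fn, x0: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of fn: R^d -> R^d at a single point."""
    d = x0.shape[0]
    J = np.zeros((d, d))
    for j in range(d):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += eps
        xm[j] -= eps
        J[:, j] = (fn(xp) - fn(xm)) / (2.0 * eps)
    return J
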