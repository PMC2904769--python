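"""Independent numerical oracles used by the test suite.

The controller oracle never touches the closed form under test: it writes
the raw single-step cost out as a function of the four noise draws, takes
its expectation by Gauss-Hermite quadrature (exact here, the cost is
quadratic in each noise variable), and minimizes that expectation
numerically along the zero-expected-error constraint line.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

# probabilists' Gauss-Hermite rule: nodes/weights for E over N(0,1)
_NODES, _WEIGHTS = np.polynomial.hermite_e.hermegauss(5)
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()
# 4-D tensor grid over (nu1, nu2, eta1, eta2)
_GRID = np.stack(np.meshgrid(*[_NODES] * 4, indexing="ij"), axis=-1).reshape(-1, 4)
_W4 = np.prod(
    np.stack(np.meshgrid(*[_WEIGHTS] * 4, indexing="ij"), axis=-1).reshape(-1, 4),
    axis=1,
)


def expected_cost_quadrature(x, u, cfg) -> float:
    """E[C(u)] under the controller's unit-gain internal model, by quadrature."""
    x = np.asarray(x, float)
    u = np.asarray(u, float)
    sm = np.asarray(cfg.sigma_mult, float)
    sa = np.asarray(cfg.sigma_add, float)
    nu = _GRID[:, :2] * sm
    eta = _GRID[:, 2:] * sa
    x_next = x + (1.0 + nu) * u + eta
    e = x_next[:, 1] - cfg.v * x_next[:, 0]
    p = x_next - cfg.x_star
    cost = (
        cfg.w_e * e**2
        + cfg.w_p * np.sum(p**2, axis=1)
        + cfg.w_u1 * u[0] ** 2
        + cfg.w_u2 * u[1] ** 2
    )
    return float(_W4 @ cost)


def brute_force_optimal_u(x, cfg) -> np.ndarray:
    """Numerically minimize E[C] subject to zero expected goal error.

    The constraint a.u = -e0 (a = (-v, 1)) is a line; parametrize it by a
    particular solution plus multiples of the tangent direction (1, v) and
    minimize the quadrature expectation over the scalar coordinate.
    """
    x = np.asarray(x, float)
    a = np.array([-cfg.v, 1.0])
    e0 = a @ x
    u_part = -e0 * a / (a @ a)
    b = np.array([1.0, cfg.v]) / np.hypot(1.0, cfg.v)
    res = minimize_scalar(
        lambda t: expected_cost_quadrature(x, u_part + t * b, cfg),
        bracket=(-1.0, 0.0, 1.0),
        method="brent",
        options={"xtol": 1e-12},
    )
    return u_part + res.x * b
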