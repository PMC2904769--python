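"""Stochastic single-step stride controllers: MIP, POP and OVC.

The walker is modeled at its stride-to-stride (Poincare) section.  The
state is ``x_n = (T_n, L_n)``; in the absence of control and noise,
successive strides of the underlying limit cycle simply repeat.  The plant
is the discrete map

    x_{n+1} = x_n + G (I + diag(nu)) u + eta

where ``u = (u1, u2)`` is the commanded stride adjustment,
``nu ~ N(0, diag(sigma_mult^2))`` is multiplicative (motor-output) noise on
the control signal, ``eta ~ N(0, diag(sigma_add^2))`` is additive
(sensory/perceptual) noise, and ``G = diag(g1, g2)`` collects extra plant
gains.  The controller always *plans* with unit gains (it believes
``G = I``); setting ``g > 1`` therefore makes every executed correction
overshoot the planned one.  That mismatch is the only thing that separates
the sub-optimal OVC variant from the optimal POP variant.

At each stride the controller minimizes the expected single-step cost

    E[C] = w_e E[e^2] + w_p E[p^2] + w_u1 u1^2 + w_u2 u2^2

subject to zero *expected* goal error at the next stride, where
``e = L - v T`` is the (linear) goal-level error of the constant-speed
strategy and ``p = ||x - (T*, L*)||`` is the distance from the preferred
operating point.  The constrained quadratic program has the closed form
implemented in :func:`optimal_control_input`.

Variants (weights as printed for the study conditions):

* ``MIP`` - pure minimum intervention: ``w_p = 0``.  Goal error is fully
  corrected in expectation each stride; nothing pulls the state along the
  GEM, so tangent deviations perform a random walk (alpha ~ 1.5).
* ``POP`` - adds a weak pull (``w_p = 2.79``) toward the preferred
  operating point ``(T*, L*) = (1.105 s, v * 1.105 m)`` at ``v = 1.21``
  m/s, standing in for energetic/biomechanical preferences.
* ``OVC`` - POP with plant gains ``g1 = g2 = 1.24``: each goal-relevant
  correction overshoots by 24%, producing anti-persistent goal-relevant
  fluctuations (alpha < 0.5), the signature seen in human data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import NonpositiveStateError
from .gait_core import (
    D_MAX_DEFAULT,
    StrideSeries,
    check_belt_constraint,
    summarize,
)

logger = logging.getLogger(__name__)

Variant = Literal["MIP", "POP", "OVC"]

_PRESETS: dict[str, dict] = {
    "MIP": {"w_p": 0.0, "g1": 1.0, "g2": 1.0},
    "POP": {"w_p": 2.79, "g1": 1.0, "g2": 1.0},
    "OVC": {"w_p": 2.79, "g1": 1.24, "g2": 1.24},
}


@dataclass(frozen=True)
class ControllerConfig:
    """Model variant, cost weights, gains, noise amplitudes and run sizes.

    Weight naming: ``w_e`` multiplies the squared goal error, ``w_p`` the
    squared distance to the preferred operating point, ``w_u1``/``w_u2``
    the squared control components.  ``sigma_mult = (sigma1, sigma2)`` are
    the multiplicative-noise SDs and ``sigma_add = (sigma3, sigma4)`` the
    additive-noise SDs, in the (T, L) component order.
    """

    variant: Variant = "OVC"
    v: float = 1.21
    Tstar: float = 1.105
    Lstar: float | None = None  # defaults to v * Tstar (a point on the GEM)
    w_e: float = 10.0
    w_p: float = 2.79
    w_u1: float = 10.0
    w_u2: float = 10.0
    g1: float = 1.24
    g2: float = 1.24
    sigma_mult: tuple[float, float] = (0.017, 0.010)
    sigma_add: tuple[float, float] = (0.017, 0.010)
    n_strides: int = 500
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Lstar is None:
            object.__setattr__(self, "Lstar", self.v * self.Tstar)
        if self.w_e <= 0:
            raise ValueError("w_e must be positive")
        if min(self.w_p, self.w_u1, self.w_u2) < 0:
            raise ValueError("cost weights must be nonnegative")
        if self.w_u1 + self.w_u2 <= 0 and self.w_p <= 0:
            raise ValueError("cost must be coercive in u (need effort or POP penalty)")
        if self.v <= 0 or self.Tstar <= 0 or self.Lstar <= 0:
            raise ValueError("v, Tstar, Lstar must be positive")
        if self.n_strides < 1 or self.n_reps < 1:
            raise ValueError("n_strides and n_reps must be >= 1")

    @classmethod
    def preset(cls, variant: str, **overrides) -> "ControllerConfig":
        """The printed parameterization of ``"MIP"``, ``"POP"`` or ``"OVC"``."""
        key = variant.upper()
        if key not in _PRESETS:
            raise ValueError(f"unknown variant {variant!r}; choose MIP, POP or OVC")
        params = dict(variant=key, **_PRESETS[key])
        params.update(overrides)
        return cls(**params)

    @property
    def x_star(self) -> np.ndarray:
        return np.array([self.Tstar, self.Lstar])

    @property
    def G(self) -> np.ndarray:
        return np.array([self.g1, self.g2])


def goal_error(x: np.ndarray, v: float) -> float:
    """Linear goal-level error ``e = L - v T`` (m); zero exactly on the GEM."""
    return float(x[1] - v * x[0])


def optimal_control_input(x: np.ndarray, cfg: ControllerConfig) -> np.ndarray:
    """Closed-form minimizer of the expected cost with zero expected goal error.

    Under the controller's internal (unit-gain) model the next state is
    ``x + (I + diag(nu)) u + eta``, so with ``a = (-v, 1)``:

        E[e^2] = (e0 + a.u)^2 + sum_i a_i^2 sigma1i^2 u_i^2 + const
        E[p^2] = ||p0 + u||^2 + sum_i sigma1i^2 u_i^2 + const

    The constraint ``a.u = -e0`` kills the first term of ``E[e^2]``; the
    rest is a diagonal quadratic ``u' A u + 2 w_p p0.u`` with
    ``A = diag(w_e a_i^2 s_i^2 + w_p s_i^2 + w_u_i + w_p)``.  A Lagrange
    multiplier on the constraint gives

        u = -A^{-1} (w_p p0 + mu a),
        mu = (e0 - w_p a'A^{-1} p0) / (a'A^{-1} a).

    At a state on the GEM with ``w_p = 0`` (MIP) this returns exactly zero:
    no intervention without goal error.
    """
    x = np.asarray(x, dtype=float)
    a = np.array([-cfg.v, 1.0])
    e0 = a @ x
    p0 = x - cfg.x_star
    s2 = np.asarray(cfg.sigma_mult, float) ** 2
    A = cfg.w_e * a**2 * s2 + cfg.w_p * s2 + np.array([cfg.w_u1, cfg.w_u2]) + cfg.w_p
    if np.any(A <= 0):  # cannot occur for valid configs; asserted defensively
        raise ArithmeticError("singular system in optimal_control_input")
    aA = a / A
    mu = (e0 - cfg.w_p * (aA @ p0)) / (aA @ a)
    return -(cfg.w_p * p0 + mu * a) / A


def expected_cost(x: np.ndarray, u: np.ndarray, cfg: ControllerConfig) -> float:
    """Expected single-step cost E[C(u)] under the controller's unit-gain model.

    Written out analytically (all four noise sources integrated); used for
    introspection and cross-checked in the test suite against a quadrature
    oracle that minimizes the raw cost numerically.
    """
    x = np.asarray(x, float)
    u = np.asarray(u, float)
    a = np.array([-cfg.v, 1.0])
    sm2 = np.asarray(cfg.sigma_mult, float) ** 2
    sa2 = np.asarray(cfg.sigma_add, float) ** 2
    e_mean = a @ x + a @ u
    E_e2 = e_mean**2 + np.sum(a**2 * sm2 * u**2) + np.sum(a**2 * sa2)
    p_mean = x + u - cfg.x_star
    E_p2 = p_mean @ p_mean + np.sum(sm2 * u**2) + np.sum(sa2)
    effort = cfg.w_u1 * u[0] ** 2 + cfg.w_u2 * u[1] ** 2
    return float(cfg.w_e * E_e2 + cfg.w_p * E_p2 + effort)


def step(x: np.ndarray, u: np.ndarray, noise_draws: np.ndarray,
         cfg: ControllerConfig) -> np.ndarray:
    """One stride of the true plant: ``x + G (I + diag(nu)) u + eta``.

    ``noise_draws = (nu1, nu2, eta1, eta2)`` are standard-normal draws,
    scaled here by ``(sigma1, sigma2, sigma3, sigma4)``.
    """
    nd = np.asarray(noise_draws, float)
    nu = nd[:2] * np.asarray(cfg.sigma_mult, float)
    eta = nd[2:] * np.asarray(cfg.sigma_add, float)
    x_next = np.asarray(x, float) + cfg.G * (1.0 + nu) * np.asarray(u, float) + eta
    if x_next[0] <= 0 or x_next[1] <= 0:
        raise NonpositiveStateError(
            f"simulated state left the positive orthant: {x_next}"
        )
    return x_next


def _rep_rng(cfg: ControllerConfig, rep_index: int, attempt: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, rep_index, attempt])


def simulate(cfg: ControllerConfig, rep_index: int = 0, attempt: int = 0) -> StrideSeries:
    """Simulate one run of ``cfg.n_strides`` strides from the operating point.

    Each (seed, rep_index, attempt) triple has its own independent RNG
    stream, so repetitions are individually reproducible.  The belt
    constraint is checked and logged; it is *not* enforced here (see
    :func:`run_model_experiment`).
    """
    rng = _rep_rng(cfg, rep_index, attempt)
    x = cfg.x_star.copy()
    out = np.empty((cfg.n_strides, 2))
    for n in range(cfg.n_strides):
        u = optimal_control_input(x, cfg)
        x = step(x, u, rng.standard_normal(4), cfg)
        out[n] = x
    series = StrideSeries(
        T=out[:, 0], L=out[:, 1], v=cfg.v,
        trial_id=f"{cfg.variant.lower()}-rep{rep_index:02d}",
        condition=cfg.variant,
    )
    belt = check_belt_constraint(series)
    if not belt.ok:
        logger.info(
            "simulated %s rep %d drifted off the belt (d_net in [%.3f, %.3f] m)",
            cfg.variant, rep_index, belt.min_d, belt.max_d,
        )
    return series


@dataclass(frozen=True)
class ModelExperimentResult:
    """Per-repetition summaries and cross-repetition contrasts for one variant."""

    config: ControllerConfig
    per_rep: pd.DataFrame
    aggregate: dict
    series: list[StrideSeries] = field(repr=False, default_factory=list)


def run_model_experiment(
    cfg: ControllerConfig,
    enforce_belt: bool = True,
    max_attempts_per_rep: int = 100,
    d_max: float = D_MAX_DEFAULT,
    dfa_settings=None,
    keep_series: bool = False,
) -> ModelExperimentResult:
    """Run ``cfg.n_reps`` simulations and aggregate the analysis outputs.

    Every repetition is summarized (mean/SD/DFA alpha of T, L, S, d_net)
    and GEM-decomposed with its own per-rep frame (SD and alpha of delta_T
    and delta_P).  With ``enforce_belt`` (default), repetitions whose net
    displacement leaves the belt are regenerated from a fresh sub-stream -
    all analyzed runs then satisfy the belt constraint, mirroring how the
    surrogate families are generated; attempts are reported per rep.

    The aggregate carries across-rep means with 95% t-confidence intervals
    and two-group one-way F statistics contrasting SD(delta_T) vs
    SD(delta_P) and alpha(delta_T) vs alpha(delta_P).
    """
    from .gem import decompose, fit_gem_frame
    from .stats import direction_anova, mean_ci

    if cfg.n_reps < 2:
        raise ValueError("run_model_experiment needs n_reps >= 2")
    rows = []
    kept: list[StrideSeries] = []
    for rep in range(cfg.n_reps):
        for attempt in range(max_attempts_per_rep):
            series = simulate(cfg, rep_index=rep, attempt=attempt)
            belt = check_belt_constraint(series, d_max)
            if belt.ok or not enforce_belt:
                break
        else:
            raise RuntimeError(
                f"rep {rep}: no belt-satisfying run in {max_attempts_per_rep} attempts"
            )
        frame = fit_gem_frame(series)
        summary = summarize(series, dfa_settings=dfa_settings, frame=frame)
        st = summary.stats
        rows.append(
            {
                "rep": rep,
                "attempts": attempt + 1,
                "belt_ok": belt.ok,
                "max_dnet": summary.max_dnet,
                "min_dnet": summary.min_dnet,
                "mean_T": st["T"].mean, "sd_T": st["T"].sd, "alpha_T": st["T"].alpha,
                "mean_L": st["L"].mean, "sd_L": st["L"].sd, "alpha_L": st["L"].alpha,
                "mean_S": st["S"].mean, "sd_S": st["S"].sd, "alpha_S": st["S"].alpha,
                "alpha_dnet": st["d_net"].alpha,
                "sd_delta_T": st["delta_T"].sd, "alpha_delta_T": st["delta_T"].alpha,
                "sd_delta_P": st["delta_P"].sd, "alpha_delta_P": st["delta_P"].alpha,
            }
        )
        if keep_series:
            kept.append(series)
    per_rep = pd.DataFrame(rows)
    aggregate: dict = {"variant": cfg.variant, "n_reps": cfg.n_reps,
                       "n_strides": cfg.n_strides,
                       "total_attempts": int(per_rep["attempts"].sum())}
    for col in ("mean_T", "mean_L", "mean_S", "sd_T", "sd_L", "sd_S",
                "sd_delta_T", "sd_delta_P", "alpha_T", "alpha_L", "alpha_S",
                "alpha_delta_T", "alpha_delta_P"):
        m, lo, hi = mean_ci(per_rep[col].to_numpy())
        aggregate[col] = m
        aggregate[f"{col}_ci95"] = (lo, hi)
    aggregate["anova_sd"] = direction_anova(
        per_rep["sd_delta_T"].to_numpy(), per_rep["sd_delta_P"].to_numpy()
    )
    aggregate["anova_alpha"] = direction_anova(
        per_rep["alpha_delta_T"].to_numpy(), per_rep["alpha_delta_P"].to_numpy()
    )
    return ModelExperimentResult(config=cfg, per_rep=per_rep, aggregate=aggregate,
                                 series=kept)
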