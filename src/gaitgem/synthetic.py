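"""Self-contained synthetic inputs: fGn-style noise, human-like trials, edge cases.

No public gait dataset accompanies the analyses this package implements, so
every stage gets a download-free input source:

* :func:`generate_fgn` - spectrally synthesized noise with a prescribed
  scaling exponent, the independent calibration oracle for DFA;
* :func:`make_humanlike_trial` - an OVC-controller walk, the mechanism the
  study itself validated as producing human-like stride statistics
  (persistent T and L, anti-persistent S, mean speed at the belt speed);
* :func:`make_adversarial_trials` - degenerate and boundary-case trials
  that exercise documented error branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .controllers import ControllerConfig, simulate
from .errors import GaitgemError
from .gait_core import StrideSeries, check_belt_constraint


class InvalidHError(GaitgemError, ValueError):
    """Requested scaling exponent outside the supported (0, 1.5] range."""


@dataclass(frozen=True)
class FgnSpec:
    """Target scaling exponent, length and seed for noise synthesis."""

    H: float
    N: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.H <= 1.5):
            raise InvalidHError(f"H must lie in (0, 1.5], got {self.H}")
        if self.N < 32:
            raise ValueError("N must be >= 32")


def _spectral_noise(H: float, N: int, rng: np.random.Generator) -> np.ndarray:
    """Fourier-filter synthesis: shape white-noise amplitudes by f^{-(2H-1)/2}."""
    white = rng.standard_normal(N)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(N)
    spectrum[1:] = spectrum[1:] * f[1:] ** (-(2.0 * H - 1.0) / 2.0)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=N)
    return (x - x.mean()) / x.std()


def generate_fgn(spec: FgnSpec) -> np.ndarray:
    """Zero-mean unit-variance noise whose DFA exponent is approximately H.

    For ``H <= 1`` the series is stationary (fGn-like); for ``H > 1`` it is
    the cumulative sum of an ``H - 1`` noise (e.g. H = 1.5 is integrated
    white noise, i.e. Brownian motion), standardized afterwards.
    """
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0xF61])
    if spec.H > 1.0:
        increments = _spectral_noise(spec.H - 1.0, spec.N, rng)
        x = np.cumsum(increments)
        return (x - x.mean()) / x.std()
    return _spectral_noise(spec.H, spec.N, rng)


def make_humanlike_trial(n_strides: int = 272, seed: int = 0) -> StrideSeries:
    """One OVC-simulated trial with human-like stride statistics.

    Defaults to 272 strides, the mean analyzed trial length of the treadmill
    experiment the controller parameters were matched to, at v = 1.21 m/s
    and T* = 1.105 s.  The returned trial is guaranteed to satisfy the belt
    constraint (violating draws are regenerated deterministically).
    """
    if not (200 <= n_strides <= 1000):
        raise ValueError("n_strides must lie in [200, 1000]")
    cfg = ControllerConfig.preset("OVC", n_strides=n_strides, seed=seed)
    for attempt in range(100):
        series = simulate(cfg, rep_index=0, attempt=attempt)
        if check_belt_constraint(series).ok:
            return StrideSeries(series.T, series.L, series.v,
                                trial_id=f"humanlike-seed{seed}", condition="OVC")
    raise RuntimeError("no belt-satisfying human-like trial in 100 attempts")


def make_adversarial_trials(v: float = 1.21) -> dict[str, StrideSeries]:
    """Fixture trials that hit documented edge cases and error branches.

    Keys
    ----
    ``constant_T``
        Constant stride times: degenerate (zero SD) for unit-variance
        normalization and for DFA.
    ``two_stride``
        Minimal length; too short for DFA and GEM fitting.
    ``belt_violation``
        Strides persistently faster than the belt; fails the belt check.
    ``on_gem``
        Every stride exactly on the GEM (L = v T): zero goal error, zero
        perpendicular deviation under the projected operating point.
    ``speed_mean_mismatch``
        Two strides constructed so mean(S) differs from (sum L)/(sum T) -
        the definition the analyses must use is the mean over S_n.
    """
    rng = np.random.default_rng(20100715)
    n = 64
    T_var = 1.1 + 0.02 * rng.standard_normal(n)
    trials = {
        "constant_T": StrideSeries(
            T=np.full(n, 1.1), L=v * 1.1 + 0.02 * rng.standard_normal(n), v=v,
            trial_id="constant_T", condition="adversarial"),
        "two_stride": StrideSeries(
            T=np.array([1.0, 1.1]), L=np.array([1.2, 1.3]), v=v,
            trial_id="two_stride", condition="adversarial"),
        "belt_violation": StrideSeries(
            T=np.full(n, 1.0), L=np.full(n, v + 0.05), v=v,
            trial_id="belt_violation", condition="adversarial"),
        "on_gem": StrideSeries(
            T=T_var, L=v * T_var, v=v,
            trial_id="on_gem", condition="adversarial"),
        "speed_mean_mismatch": StrideSeries(
            T=np.array([1.0, 2.0]), L=np.array([2.0, 2.0]), v=v,
            trial_id="speed_mean_mismatch", condition="adversarial"),
    }
    return trials
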