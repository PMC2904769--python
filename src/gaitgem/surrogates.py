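"""Surrogate stride series: null models of GEM-ignorant walking.

Three families, each a randomized transform of an observed trial that
preserves chosen properties while destroying others, used to test whether
the temporal structure of real stride data could have come from a control
strategy that never references the constant-speed goal:

``shuffle``
    Independent random permutations of the stride-time and stride-length
    series.  Preserves each marginal distribution exactly; destroys temporal
    order and the T-L coupling.
``phase_randomized``
    Theiler phase randomization applied to T and L separately: Fourier
    amplitudes (hence the periodogram and all linear autocorrelations) are
    preserved, phases are drawn iid uniform.  Destroys the T-L coupling and
    any nonlinear structure.
``paired_shuffle``
    One permutation applied jointly to (T, L) pairs.  Preserves the stride
    point cloud - hence all stride speeds and the delta_T/delta_P variance
    ratio - exactly; destroys temporal order.

Every surrogate that is actually *used* must itself be a walkable trial:
positive stride times/lengths and a net displacement that stays on the
belt.  :func:`generate_valid_surrogates` enforces this by rejection
sampling with a capped, reported attempt budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ConstraintUnsatisfiableError, InvalidSeriesError
from .gait_core import D_MAX_DEFAULT, StrideSeries, check_belt_constraint

SurrogateKind = Literal["shuffle", "phase_randomized", "paired_shuffle"]


@dataclass(frozen=True)
class SurrogateConfig:
    """How many surrogates of which family, under which belt constraint."""

    kind: SurrogateKind = "shuffle"
    n_surrogates: int = 20
    d_max: float = D_MAX_DEFAULT
    max_attempts_per_surrogate: int = 1000
    seed: int = 0
    #: phase-randomized only: reuse one phase vector for both T and L
    shared_phases: bool = False

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.max_attempts_per_surrogate < 1:
            raise ValueError("max_attempts_per_surrogate must be >= 1")


def shuffle_surrogate(series: StrideSeries, rng: np.random.Generator) -> StrideSeries:
    """Independent uniform random permutations of T and of L."""
    if series.n_strides == 1:
        return series
    T = series.T[rng.permutation(series.n_strides)]
    L = series.L[rng.permutation(series.n_strides)]
    return series.with_values(T, L, condition="surrogate/shuffle")


def paired_shuffle_surrogate(series: StrideSeries, rng: np.random.Generator) -> StrideSeries:
    """One permutation applied jointly to the (T, L) pairs."""
    if series.n_strides == 1:
        return series
    perm = rng.permutation(series.n_strides)
    return series.with_values(series.T[perm], series.L[perm],
                              condition="surrogate/paired_shuffle")


def phase_randomized_surrogate(x: np.ndarray, rng: np.random.Generator,
                               phases: np.ndarray | None = None) -> np.ndarray:
    """Theiler phase-randomized copy of a 1-D sequence.

    The DC component (the mean) is untouched and, for even length, the
    Nyquist bin keeps its real value; all other rFFT bins get iid uniform
    phases (conjugate symmetry is implicit in the real inverse transform).
    The periodogram of the output equals that of the input.

    Parameters
    ----------
    phases : ndarray, optional
        Pre-drawn uniform phases for the free bins; used to apply the same
        randomization to several series.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < 8:
        raise InvalidSeriesError("phase randomization needs at least 8 samples")
    mean = x.mean()
    spectrum = np.fft.rfft(x - mean)
    n_bins = spectrum.size
    # free bins: everything but DC, and but Nyquist when N is even
    hi = n_bins - 1 if N % 2 == 0 else n_bins
    n_free = hi - 1
    if phases is None:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_free)
    elif phases.size != n_free:
        raise ValueError(f"expected {n_free} phases, got {phases.size}")
    randomized = spectrum.copy()
    randomized[1:hi] = np.abs(spectrum[1:hi]) * np.exp(1j * phases)
    return np.fft.irfft(randomized, n=N) + mean


def n_free_phases(N: int) -> int:
    """Number of independently randomizable rFFT bins for length ``N``."""
    n_bins = N // 2 + 1
    return (n_bins - 1 if N % 2 == 0 else n_bins) - 1


def _phase_randomized_series(series: StrideSeries, rng: np.random.Generator,
                             shared_phases: bool) -> StrideSeries:
    if shared_phases:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_free_phases(series.n_strides))
        T = phase_randomized_surrogate(series.T, rng, phases=phases)
        L = phase_randomized_surrogate(series.L, rng, phases=phases)
    else:
        T = phase_randomized_surrogate(series.T, rng)
        L = phase_randomized_surrogate(series.L, rng)
    if np.any(T <= 0) or np.any(L <= 0):
        # signal to the rejection loop without constructing an invalid series
        raise InvalidSeriesError("phase-randomized draw left the positive orthant")
    return series.with_values(T, L, condition="surrogate/phase_randomized")


@dataclass
class GenerationReport:
    """Bookkeeping from the rejection-sampling loop."""

    kind: str
    n_surrogates: int
    attempts: list[int] = field(default_factory=list)
    n_belt_rejections: int = 0
    n_positivity_rejections: int = 0

    @property
    def total_attempts(self) -> int:
        return int(sum(self.attempts))


def generate_valid_surrogates(
    series: StrideSeries, cfg: SurrogateConfig
) -> tuple[list[StrideSeries], GenerationReport]:
    """Draw ``cfg.n_surrogates`` surrogates that are themselves valid trials.

    Each accepted surrogate has strictly positive stride times and lengths
    and satisfies the belt constraint with ``cfg.d_max``.  Violating draws
    are rejected and regenerated, up to ``cfg.max_attempts_per_surrogate``
    attempts each.

    Raises
    ------
    InvalidSeriesError
        If the original series itself violates the belt constraint.
    ConstraintUnsatisfiableError
        If some surrogate exhausts its attempt budget.
    """
    if not check_belt_constraint(series, cfg.d_max).ok:
        raise InvalidSeriesError(
            "original trial violates the belt constraint; surrogates are undefined"
        )
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x5AE])
    report = GenerationReport(kind=cfg.kind, n_surrogates=cfg.n_surrogates)
    out: list[StrideSeries] = []
    for _ in range(cfg.n_surrogates):
        attempts = 0
        while True:
            attempts += 1
            if attempts > cfg.max_attempts_per_surrogate:
                raise ConstraintUnsatisfiableError(
                    f"no valid {cfg.kind} surrogate within "
                    f"{cfg.max_attempts_per_surrogate} attempts"
                )
            try:
                if cfg.kind == "shuffle":
                    cand = shuffle_surrogate(series, rng)
                elif cfg.kind == "paired_shuffle":
                    cand = paired_shuffle_surrogate(series, rng)
                elif cfg.kind == "phase_randomized":
                    cand = _phase_randomized_series(series, rng, cfg.shared_phases)
                else:
                    raise ValueError(f"unknown surrogate kind {cfg.kind!r}")
            except InvalidSeriesError:
                report.n_positivity_rejections += 1
                continue
            if check_belt_constraint(cand, cfg.d_max).ok:
                break
            report.n_belt_rejections += 1
        report.attempts.append(attempts)
        out.append(cand)
    return out, report
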