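"""First-order detrended fluctuation analysis (DFA-1).

DFA estimates the scaling exponent ``alpha`` of a time series: the log-log
slope of the detrended fluctuation magnitude ``F(n)`` against box size
``n``.  For stride series, ``alpha > 1/2`` marks statistical persistence
(deviations tend to be followed by deviations of the same sign),
``alpha < 1/2`` anti-persistence, ``alpha = 1/2`` uncorrelated noise, and
``alpha = 3/2`` Brownian motion (integrated white noise).

Algorithm (canonical DFA-1): integrate the mean-removed series, cut the
profile into non-overlapping boxes of size ``n`` starting from the first
sample, remove a least-squares polynomial of order ``detrend_order`` from
each box, and pool the residuals into the RMS fluctuation ``F(n)``.
``alpha`` is the unweighted least-squares slope of ``log10 F`` on
``log10 n`` over all box sizes (no crossover segmentation: one exponent
per series).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import ConstantInputError, TooShortSeriesError

Boxing = Literal["forward", "both"]


@dataclass(frozen=True)
class DfaSettings:
    """Box layout and detrending options.

    The default layout uses ~16 log-uniformly spaced integer box sizes in
    ``[4, N//4]``: 4 is the smallest box where a linear fit leaves at least
    two residual degrees of freedom, and ``N//4`` guarantees at least four
    boxes are averaged at the largest scale.  ``boxing="both"`` additionally
    tiles boxes from the end of the profile so the tail remainder is not
    discarded.
    """

    min_box: int = 4
    n_sizes: int = 16
    detrend_order: int = 1
    boxing: Boxing = "forward"


@dataclass(frozen=True)
class DfaResult:
    """Fluctuation function and fitted scaling exponent for one series."""

    box_sizes: np.ndarray
    F: np.ndarray
    alpha: float
    fit_intercept: float
    r_squared: float
    n_points_fit: int


def default_box_sizes(N: int, min_box: int = 4, n_sizes: int = 16) -> np.ndarray:
    """~``n_sizes`` log-uniformly spaced integer box sizes in [min_box, N//4].

    Duplicates after integer rounding are collapsed; fewer than six distinct
    sizes raises :class:`TooShortSeriesError`.
    """
    if N < 16:
        raise TooShortSeriesError(f"series of length {N} is too short for DFA")
    max_box = N // 4
    if max_box < min_box:
        raise TooShortSeriesError(f"series of length {N} allows no box in [{min_box}, N//4]")
    sizes = np.unique(
        np.round(
            np.exp(np.linspace(np.log(min_box), np.log(max_box), n_sizes))
        ).astype(int)
    )
    if sizes.size < 6:
        raise TooShortSeriesError(
            f"only {sizes.size} distinct box sizes available for N={N}; need >= 6"
        )
    return sizes


def _box_fluctuation(profile: np.ndarray, n: int, order: int, boxing: Boxing) -> float:
    """Pooled mean squared residual for box size ``n``. Returns MS, not RMS."""
    N = profile.size
    k = N // n
    segments = [profile[: k * n].reshape(k, n)]
    if boxing == "both" and k * n < N:
        segments.append(profile[N - k * n:].reshape(k, n))
    t = np.arange(n, dtype=float)
    # shared design matrix across boxes: one lstsq per box size
    X = np.vander(t, order + 1, increasing=True)
    pinv = np.linalg.pinv(X)
    ms_parts = []
    for seg in segments:
        coef = seg @ pinv.T
        resid = seg - coef @ X.T
        ms_parts.append(np.mean(resid**2))
    return float(np.mean(ms_parts))


def dfa(
    x: Sequence[float] | np.ndarray,
    box_sizes: Sequence[int] | np.ndarray | None = None,
    detrend_order: int | None = None,
    settings: DfaSettings | None = None,
) -> DfaResult:
    """Compute the DFA scaling exponent of a series.

    Parameters
    ----------
    x : sequence of float
        The series to analyze (e.g. stride times or GEM deviations).
    box_sizes : sequence of int, optional
        Explicit box sizes; defaults to :func:`default_box_sizes`.
    detrend_order : int, optional
        Polynomial order removed per box; overrides ``settings``.
    settings : DfaSettings, optional
        Box layout and boxing direction.

    Raises
    ------
    ConstantInputError
        If the input is constant (all fluctuations vanish).
    TooShortSeriesError
        If fewer than two boxes fit at some requested size.
    """
    settings = settings if settings is not None else DfaSettings()
    order = settings.detrend_order if detrend_order is None else detrend_order
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("dfa expects a one-dimensional series")
    N = x.size
    if np.ptp(x) == 0.0:
        raise ConstantInputError("DFA is undefined for a constant series")
    if box_sizes is None:
        sizes = default_box_sizes(N, min_box=settings.min_box, n_sizes=settings.n_sizes)
    else:
        sizes = np.unique(np.asarray(box_sizes, dtype=int))
        if sizes.size == 0 or sizes[0] < order + 3:
            raise ValueError(f"box sizes must leave >=2 residual dof (min {order + 3})")
    if N // sizes[-1] < 2:
        raise TooShortSeriesError(
            f"largest box {sizes[-1]} does not fit twice into series of length {N}"
        )
    profile = np.cumsum(x - x.mean())
    F = np.sqrt([_box_fluctuation(profile, int(n), order, settings.boxing) for n in sizes])
    if np.any(F == 0.0):
        raise ConstantInputError("zero fluctuation at some box size; series is degenerate")
    logn = np.log10(sizes)
    logF = np.log10(F)
    alpha, intercept = np.polyfit(logn, logF, 1)
    corr = np.corrcoef(logn, logF)[0, 1]
    return DfaResult(
        box_sizes=sizes,
        F=F,
        alpha=float(alpha),
        fit_intercept=float(intercept),
        r_squared=float(corr**2),
        n_points_fit=int(sizes.size),
    )
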