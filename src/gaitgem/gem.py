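"""Goal Equivalent Manifold (GEM) frame and coordinate transform.

Constant-speed treadmill walking admits a one-parameter family of perfect
strides: every (T, L) pair with L = v*T keeps the walker exactly on belt
speed.  That line is the goal equivalent manifold.  After normalizing each
stride variable to unit variance, deviations of a stride from the operating
point (T*, L*) are rotated into components tangent to the GEM (``delta_T``,
goal-equivalent: they do not change stride speed) and perpendicular to it
(``delta_P``, goal-relevant: they do).

In normalized coordinates the GEM has slope ``m_hat = v * sigma_T / sigma_L``
and the orthonormal basis is

    e_T = (1, m_hat) / sqrt(1 + m_hat^2)
    e_P = (-m_hat, 1) / sqrt(1 + m_hat^2)

with the sign of ``e_P`` chosen so that ``delta_P > 0`` means the stride was
faster than the belt.  SDs and DFA exponents are invariant to that choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DegenerateSeriesError, InvalidSeriesError
from .gait_core import StrideSeries

Normalization = Literal["per-series-sd", "none"]
OperatingPoint = Literal["sample-mean", "projected-to-gem"]


@dataclass(frozen=True)
class GemFrame:
    """Normalization scales, operating point and tangent/perpendicular basis."""

    sigma_T: float
    sigma_L: float
    v: float
    Tstar: float
    Lstar: float
    m_hat: float
    e_T: np.ndarray
    e_P: np.ndarray

    def __post_init__(self) -> None:
        e_T = np.asarray(self.e_T, float)
        e_P = np.asarray(self.e_P, float)
        e_T.flags.writeable = False
        e_P.flags.writeable = False
        object.__setattr__(self, "e_T", e_T)
        object.__setattr__(self, "e_P", e_P)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sigma_T": self.sigma_T,
                "sigma_L": self.sigma_L,
                "v": self.v,
                "Tstar": self.Tstar,
                "Lstar": self.Lstar,
                "m_hat": self.m_hat,
                "e_T": self.e_T.tolist(),
                "e_P": self.e_P.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GemFrame":
        d = json.loads(text)
        return cls(
            sigma_T=d["sigma_T"], sigma_L=d["sigma_L"], v=d["v"],
            Tstar=d["Tstar"], Lstar=d["Lstar"], m_hat=d["m_hat"],
            e_T=np.asarray(d["e_T"], float), e_P=np.asarray(d["e_P"], float),
        )


@dataclass(frozen=True)
class GemDeviations:
    """Dimensionless goal-equivalent (delta_T) and goal-relevant (delta_P) series."""

    delta_T: np.ndarray
    delta_P: np.ndarray
    frame: GemFrame

    def __post_init__(self) -> None:
        dT = np.asarray(self.delta_T, float)
        dP = np.asarray(self.delta_P, float)
        if dT.shape != dP.shape or dT.ndim != 1:
            raise InvalidSeriesError("delta_T and delta_P must be equal-length 1-D arrays")
        dT.flags.writeable = False
        dP.flags.writeable = False
        object.__setattr__(self, "delta_T", dT)
        object.__setattr__(self, "delta_P", dP)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stride": np.arange(1, self.delta_T.size + 1),
                "delta_T": self.delta_T,
                "delta_P": self.delta_P,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        """Deviations as CSV next to the frame serialized as JSON."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.12g")
        path.with_suffix(".frame.json").write_text(self.frame.to_json(), encoding="utf-8")


def fit_gem_frame(
    series: StrideSeries,
    normalization: Normalization = "per-series-sd",
    operating_point: OperatingPoint = "sample-mean",
) -> GemFrame:
    """Fit the trial-local GEM frame.

    With ``normalization="per-series-sd"`` each variable is scaled by its own
    sample SD (the trial then has unit variance in both axes); ``"none"``
    keeps physical units.  The operating point is either the sample mean of
    (T, L) or its projection onto the GEM along the L axis (``L* = v T*``).

    Raises
    ------
    DegenerateSeriesError
        If a variable has zero variance under per-series-SD normalization.
    """
    if series.n_strides < 3:
        raise InvalidSeriesError("need at least 3 strides to fit a GEM frame")
    if normalization == "per-series-sd":
        sigma_T = float(np.std(series.T, ddof=1))
        sigma_L = float(np.std(series.L, ddof=1))
        # relative threshold: a constant series can carry ~1e-16 rounding noise
        if sigma_T <= 1e-12 * abs(np.mean(series.T)) or \
                sigma_L <= 1e-12 * abs(np.mean(series.L)):
            raise DegenerateSeriesError(
                "zero-variance stride series cannot be normalized to unit variance"
            )
    elif normalization == "none":
        sigma_T = sigma_L = 1.0
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    Tstar = float(np.mean(series.T))
    if operating_point == "sample-mean":
        Lstar = float(np.mean(series.L))
    elif operating_point == "projected-to-gem":
        Lstar = series.v * Tstar
    else:
        raise ValueError(f"unknown operating_point {operating_point!r}")
    m_hat = series.v * sigma_T / sigma_L
    norm = np.hypot(1.0, m_hat)
    e_T = np.array([1.0, m_hat]) / norm
    e_P = np.array([-m_hat, 1.0]) / norm
    return GemFrame(
        sigma_T=sigma_T, sigma_L=sigma_L, v=series.v,
        Tstar=Tstar, Lstar=Lstar, m_hat=m_hat, e_T=e_T, e_P=e_P,
    )


def decompose(series: StrideSeries, frame: GemFrame) -> GemDeviations:
    """Transform strides into (delta_T, delta_P) deviations in the frame."""
    Tp = series.T / frame.sigma_T - frame.Tstar / frame.sigma_T
    Lp = series.L / frame.sigma_L - frame.Lstar / frame.sigma_L
    delta_T = frame.e_T[0] * Tp + frame.e_T[1] * Lp
    delta_P = frame.e_P[0] * Tp + frame.e_P[1] * Lp
    return GemDeviations(delta_T=delta_T, delta_P=delta_P, frame=frame)


def reconstruct(dev: GemDeviations, trial_id: str = "", condition: str = "reconstructed") -> StrideSeries:
    """Invert :func:`decompose`: map deviations back to physical strides."""
    frame = dev.frame
    Tp = dev.delta_T * frame.e_T[0] + dev.delta_P * frame.e_P[0]
    Lp = dev.delta_T * frame.e_T[1] + dev.delta_P * frame.e_P[1]
    T = (Tp + frame.Tstar / frame.sigma_T) * frame.sigma_T
    L = (Lp + frame.Lstar / frame.sigma_L) * frame.sigma_L
    return StrideSeries(T=T, L=L, v=frame.v, trial_id=trial_id, condition=condition)
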