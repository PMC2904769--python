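"""Stride-series data model, derived quantities, summaries and file I/O.

The in-memory unit of analysis is a :class:`StrideSeries`: one treadmill
trial sampled at its stride-to-stride (Poincare) section, i.e. one row per
stride holding the stride time ``T_n`` (s) and stride length ``L_n`` (m),
plus the belt speed ``v`` (m/s).  Stride speed ``S_n = L_n / T_n`` is always
derived, never stored, so the three can never disagree.

Files are plain CSV with ``#``-prefixed ``key=value`` metadata lines
(``v``, ``trial_id``, ``condition``) before a ``stride,T_s,L_m`` header.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidSeriesError, MalformedFileError

#: Half the length of the treadmill belt (m); a walker whose net displacement
#: leaves [-D_MAX_DEFAULT, +D_MAX_DEFAULT] has walked off the belt.
D_MAX_DEFAULT = 0.864


@dataclass(frozen=True)
class StrideSeries:
    """One walking trial: per-stride times and lengths at fixed belt speed.

    Parameters
    ----------
    T : array-like of float
        Stride times in seconds, strictly positive.
    L : array-like of float
        Stride lengths in meters, strictly positive, same length as ``T``.
    v : float
        Treadmill belt speed in m/s, strictly positive.
    trial_id, condition : str
        Free-form labels carried through analyses and files.
    """

    T: np.ndarray
    L: np.ndarray
    v: float
    trial_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        L = np.asarray(self.L, dtype=float)
        if T.ndim != 1 or L.ndim != 1:
            raise InvalidSeriesError("T and L must be one-dimensional")
        if T.shape != L.shape:
            raise InvalidSeriesError(
                f"T and L must have equal length (got {T.size} and {L.size})"
            )
        if T.size < 1:
            raise InvalidSeriesError("a stride series needs at least one stride")
        if not (np.all(np.isfinite(T)) and np.all(np.isfinite(L))):
            raise InvalidSeriesError("T and L must be finite")
        if np.any(T <= 0) or np.any(L <= 0):
            raise InvalidSeriesError("stride times and lengths must be positive")
        if not (math.isfinite(self.v) and self.v > 0):
            raise InvalidSeriesError("belt speed v must be positive and finite")
        T.flags.writeable = False
        L.flags.writeable = False
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "L", L)

    @property
    def n_strides(self) -> int:
        return int(self.T.size)

    @property
    def S(self) -> np.ndarray:
        """Stride speeds ``S_n = L_n / T_n`` (m/s), computed lazily."""
        return stride_speeds(self)

    def with_values(self, T: np.ndarray, L: np.ndarray, condition: str | None = None) -> "StrideSeries":
        """New series with the same belt speed and labels but new samples."""
        return StrideSeries(
            T=T, L=L, v=self.v, trial_id=self.trial_id,
            condition=self.condition if condition is None else condition,
        )


def stride_speeds(series: StrideSeries) -> np.ndarray:
    """Element-wise stride speeds ``S_n = L_n / T_n`` in m/s."""
    return series.L / series.T


def dnet(series: StrideSeries) -> np.ndarray:
    """Net cumulative displacement relative to the belt center, in meters.

    ``d_net(n) = sum_{i<=n} (L_i - v * T_i)``; ``d_net(0) = 0`` is the belt
    center and is not included in the returned length-N array.  Positive
    values are forward (toward the front of the treadmill).
    """
    return np.cumsum(series.L - series.v * series.T)


@dataclass(frozen=True)
class BeltCheck:
    """Outcome of the do-not-walk-off check for one trial."""

    ok: bool
    max_d: float
    min_d: float
    d_max: float


def check_belt_constraint(series: StrideSeries, d_max: float = D_MAX_DEFAULT) -> BeltCheck:
    """Check that the walker's net displacement stays on the belt.

    The walker starts at the belt center (``d_net = 0``), so the extremes
    include the starting position.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    d = dnet(series)
    max_d = float(max(d.max(), 0.0))
    min_d = float(min(d.min(), 0.0))
    return BeltCheck(ok=(-d_max <= min_d and max_d <= d_max), max_d=max_d,
                     min_d=min_d, d_max=float(d_max))


# ---------------------------------------------------------------------------
# File I/O

_HEADER = ["stride", "T_s", "L_m"]


def write_stride_csv(series: StrideSeries, path: str | Path) -> None:
    """Write a stride series to CSV, lossless to 12 significant digits."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# v={series.v!r}\n")
        fh.write(f"# trial_id={series.trial_id}\n")
        fh.write(f"# condition={series.condition}\n")
        fh.write(",".join(_HEADER) + "\n")
        for i, (t, l) in enumerate(zip(series.T, series.L), start=1):
            fh.write(f"{i},{t:.12g},{l:.12g}\n")


def read_stride_csv(path: str | Path) -> StrideSeries:
    """Read a stride series written by :func:`write_stride_csv`.

    Raises
    ------
    MalformedFileError
        On missing columns, non-numeric entries, nonpositive values, or a
        missing/invalid belt speed.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise MalformedFileError(f"cannot read {path}: {exc}") from exc
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise MalformedFileError(f"{path}: no data rows")
    try:
        df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    except Exception as exc:  # pandas raises several parser error types
        raise MalformedFileError(f"{path}: {exc}") from exc
    missing = [c for c in _HEADER if c not in df.columns]
    if missing:
        raise MalformedFileError(f"{path}: missing columns {missing}")
    for col in ("T_s", "L_m"):
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            raise MalformedFileError(f"{path}: non-numeric value in column {col}")
        if (values <= 0).any():
            raise MalformedFileError(f"{path}: nonpositive value in column {col}")
    try:
        v = float(meta["v"])
    except (KeyError, ValueError) as exc:
        raise MalformedFileError(f"{path}: missing or invalid belt speed metadata") from exc
    if v <= 0:
        raise MalformedFileError(f"{path}: belt speed must be positive")
    return StrideSeries(
        T=df["T_s"].to_numpy(dtype=float),
        L=df["L_m"].to_numpy(dtype=float),
        v=v,
        trial_id=meta.get("trial_id", ""),
        condition=meta.get("condition", ""),
    )


# ---------------------------------------------------------------------------
# Summaries

@dataclass(frozen=True)
class VariableStats:
    """Mean, dispersion and DFA scaling exponent of one stride variable.

    ``alpha`` is NaN when the variable is constant (degenerate for DFA) or
    when DFA was not requested.
    """

    mean: float
    sd: float
    alpha: float


@dataclass(frozen=True)
class TrialSummary:
    """Per-trial summary: stats for T, L, S, d_net and optionally delta_T/P."""

    trial_id: str
    condition: str
    n_strides: int
    stats: Mapping[str, VariableStats]
    max_dnet: float
    min_dnet: float

    def to_tidy(self) -> pd.DataFrame:
        """One row per (trial, variable): tidy layout for aggregation."""
        rows = [
            {
                "trial_id": self.trial_id,
                "condition": self.condition,
                "variable": name,
                "mean": vs.mean,
                "sd": vs.sd,
                "alpha": vs.alpha,
                "n_strides": self.n_strides,
            }
            for name, vs in self.stats.items()
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "trial_id": self.trial_id,
            "condition": self.condition,
            "n_strides": self.n_strides,
            "max_dnet": self.max_dnet,
            "min_dnet": self.min_dnet,
            "stats": {
                name: {"mean": vs.mean, "sd": vs.sd, "alpha": vs.alpha}
                for name, vs in self.stats.items()
            },
        }
        return json.dumps(payload, indent=2, allow_nan=True)


def _stats_for(x: np.ndarray, dfa_settings, compute_alpha: bool) -> VariableStats:
    from .dfa import DfaSettings, dfa
    from .errors import ConstantInputError, TooShortSeriesError

    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    alpha = float("nan")
    # a numerically-constant variable (e.g. delta_P of an exactly on-GEM
    # trial) is degenerate for DFA even when rounding leaves sd > 0
    if sd <= 1e-12 * max(1.0, abs(mean), float(np.max(np.abs(x)))):
        compute_alpha = False
    if compute_alpha:
        settings = dfa_settings if dfa_settings is not None else DfaSettings()
        try:
            alpha = dfa(x, settings=settings).alpha
        except (ConstantInputError, TooShortSeriesError):
            alpha = float("nan")
    return VariableStats(mean=mean, sd=sd, alpha=alpha)


def summarize(series: StrideSeries, dfa_settings=None, frame=None,
              compute_alpha: bool = True) -> TrialSummary:
    """Means, SDs and DFA exponents of all primary stride variables.

    Covers ``T``, ``L``, ``S`` and ``d_net``; when a fitted GEM ``frame`` is
    supplied the goal-equivalent/goal-relevant deviations ``delta_T`` and
    ``delta_P`` are included as well.  Variables that are constant get
    ``alpha = NaN`` (DFA is undefined on them).
    """
    d = dnet(series)
    variables: dict[str, np.ndarray] = {
        "T": series.T,
        "L": series.L,
        "S": stride_speeds(series),
        "d_net": d,
    }
    if frame is not None:
        from .gem import decompose

        dev = decompose(series, frame)
        variables["delta_T"] = dev.delta_T
        variables["delta_P"] = dev.delta_P
    stats = {
        name: _stats_for(np.asarray(x, float), dfa_settings, compute_alpha)
        for name, x in variables.items()
    }
    return TrialSummary(
        trial_id=series.trial_id,
        condition=series.condition,
        n_strides=series.n_strides,
        stats=stats,
        max_dnet=float(max(d.max(), 0.0)),
        min_dnet=float(min(d.min(), 0.0)),
    )
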