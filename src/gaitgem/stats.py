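"""Small statistical helpers shared by the pipeline and model experiments."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Sample mean with a two-sided t-distribution confidence interval."""
    values = np.asarray(values, dtype=float)
    n = values.size
    m = float(np.mean(values))
    if n < 2:
        return m, float("nan"), float("nan")
    half = float(sps.t.ppf(0.5 + level / 2.0, df=n - 1) * sps.sem(values))
    return m, m - half, m + half


def direction_anova(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Two-group one-way ANOVA F statistic (equivalently a squared t test).

    Used to contrast a per-repetition dependent measure between the two GEM
    directions (delta_T vs delta_P), e.g. the 20 per-rep SDs or DFA
    exponents of a model experiment.  Returns ``F``, ``df = (1, 2n-2)``,
    the p-value, and a ``degenerate`` flag set when the within-group
    variance vanishes (identical groups give F = 0 with the flag raised).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("direction_anova expects equal-sized groups")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 observations per group")
    grand = (a.sum() + b.sum()) / (2 * n)
    ss_between = n * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
    ss_within = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    df = (1, 2 * n - 2)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return {"F": 0.0, "df": df, "p": 1.0, "degenerate": True}
        return {"F": float("inf"), "df": df, "p": 0.0, "degenerate": True}
    F = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(F, *df))
    return {"F": float(F), "df": df, "p": p, "degenerate": False}
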