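"""End-to-end orchestration: per-trial analysis and surrogate comparisons.

This is the layer the analysis drivers and the CLI sit on: it wires the
GEM decomposition, DFA and surrogate generators together for one trial and
emits tidy tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dfa import DfaSettings
from .gait_core import StrideSeries, TrialSummary, summarize
from .gem import GemDeviations, Normalization, OperatingPoint, decompose, fit_gem_frame
from .stats import direction_anova, mean_ci  # noqa: F401  (public re-export)
from .surrogates import SurrogateConfig, generate_valid_surrogates

#: variables compared between an original trial and its surrogates
_SURROGATE_VARIABLES = ("T", "L", "S", "delta_T", "delta_P")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (inputs, settings, seeding)."""

    inputs: tuple[str, ...] = ()
    preset: str | None = None
    dfa: DfaSettings = field(default_factory=DfaSettings)
    normalization: Normalization = "per-series-sd"
    operating_point: OperatingPoint = "sample-mean"
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"


def analyze_trial(
    series: StrideSeries,
    dfa_settings: DfaSettings | None = None,
    normalization: Normalization = "per-series-sd",
    operating_point: OperatingPoint = "sample-mean",
) -> tuple[TrialSummary, GemDeviations]:
    """Full single-trial analysis: GEM frame, decomposition, DFA on everything.

    Returns the summary (mean/SD/alpha for T, L, S, d_net, delta_T,
    delta_P) together with the deviation series for export or plotting.
    """
    frame = fit_gem_frame(series, normalization=normalization,
                          operating_point=operating_point)
    dev = decompose(series, frame)
    summary = summarize(series, dfa_settings=dfa_settings, frame=frame)
    return summary, dev


def _trial_row(series: StrideSeries, dfa_settings, normalization, operating_point) -> dict:
    summary, _ = analyze_trial(series, dfa_settings, normalization, operating_point)
    row: dict = {}
    for var in _SURROGATE_VARIABLES:
        row[f"sd_{var}"] = summary.stats[var].sd
        row[f"alpha_{var}"] = summary.stats[var].alpha
    return row


def compare_surrogates(
    series: StrideSeries,
    cfg: SurrogateConfig,
    dfa_settings: DfaSettings | None = None,
    normalization: Normalization = "per-series-sd",
    operating_point: OperatingPoint = "sample-mean",
) -> pd.DataFrame:
    """Surrogate-averaged dependent measures next to the original trial's.

    Generates ``cfg.n_surrogates`` belt-valid surrogates, analyzes each one
    exactly like a real trial (its own GEM frame, DFA on all variables) and
    averages each dependent measure over the surrogates - the per-trial
    summary convention of surrogate testing.  Returns a tidy table with one
    row per (variable, measure) and columns ``original``,
    ``surrogate_mean``, ``surrogate_sd``.
    """
    surrogates, report = generate_valid_surrogates(series, cfg)
    original = _trial_row(series, dfa_settings, normalization, operating_point)
    per_surrogate = pd.DataFrame(
        [_trial_row(s, dfa_settings, normalization, operating_point) for s in surrogates]
    )
    rows = []
    for var in _SURROGATE_VARIABLES:
        for measure in ("sd", "alpha"):
            col = f"{measure}_{var}"
            rows.append(
                {
                    "kind": cfg.kind,
                    "variable": var,
                    "measure": measure,
                    "original": original[col],
                    "surrogate_mean": float(per_surrogate[col].mean()),
                    "surrogate_sd": float(per_surrogate[col].std(ddof=1)),
                    "n_surrogates": cfg.n_surrogates,
                    "total_attempts": report.total_attempts,
                }
            )
    return pd.DataFrame(rows)


def model_contrast_table(results: dict[str, "object"]) -> pd.DataFrame:
    """Across-variant contrast of the GEM-direction statistics.

    ``results`` maps variant name to a
    :class:`~gaitgem.controllers.ModelExperimentResult`; the returned table
    has one row per variant with the across-rep mean SDs and alphas in both
    GEM directions plus the direction F statistics.
    """
    rows = []
    for name, res in results.items():
        agg = res.aggregate
        rows.append(
            {
                "variant": name,
                "sd_delta_T": agg["sd_delta_T"],
                "sd_delta_P": agg["sd_delta_P"],
                "alpha_delta_T": agg["alpha_delta_T"],
                "alpha_delta_P": agg["alpha_delta_P"],
                "F_sd": agg["anova_sd"]["F"],
                "p_sd": agg["anova_sd"]["p"],
                "F_alpha": agg["anova_alpha"]["F"],
                "p_alpha": agg["anova_alpha"]["p"],
            }
        )
    return pd.DataFrame(rows)
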