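"""Simulate the three stride controllers and contrast their GEM dynamics.

Runs the MIP, POP and OVC presets (20 runs x 500 strides each, printed
parameters: v = 1.21 m/s, T* = 1.105 s, sigma = 0.017/0.010, beta = 2.79
for POP/OVC, g = 1.24 for OVC), GEM-decomposes every run with its own
frame, and writes per-run summaries plus the across-model contrast table.

Expected pattern: MIP shows Brownian tangent drift (alpha(delta_T) ~ 1.5)
with uncorrelated goal-relevant deviations (alpha(delta_P) ~ 0.5); POP
tempers the drift but keeps alpha(delta_P) ~ 0.5; only OVC's
over-correcting gains push alpha(delta_P) below 0.5, the anti-persistent
signature of human walking.
"""

import argparse
import json
from pathlib import Path

from gaitgem import ControllerConfig, run_model_experiment
from gaitgem.pipeline import model_contrast_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    RESULTS.mkdir(exist_ok=True)
    results = {}
    for variant in ("MIP", "POP", "OVC"):
        cfg = ControllerConfig.preset(variant, seed=args.seed)
        res = run_model_experiment(cfg)
        results[variant] = res
        res.per_rep.to_csv(RESULTS / f"model_{variant.lower()}_per_rep.csv",
                           index=False, float_format="%.6g")
        agg = res.aggregate
        print(
            f"{variant}: alpha(delta_T)={agg['alpha_delta_T']:.3f}, "
            f"alpha(delta_P)={agg['alpha_delta_P']:.3f}, "
            f"SD ratio={agg['sd_delta_T'] / agg['sd_delta_P']:.2f}, "
            f"mean S={agg['mean_S']:.4f} m/s, "
            f"belt attempts={agg['total_attempts']}"
        )
        (RESULTS / f"model_{variant.lower()}_aggregate.json").write_text(
            json.dumps(agg, indent=2, default=str), encoding="utf-8"
        )

    table = model_contrast_table(results)
    table.to_csv(RESULTS / "model_contrast.csv", index=False, float_format="%.6g")
    print("\nContrast table (results/model_contrast.csv):")
    print(table.to_string(index=False))
    anti = table.set_index("variant").loc["OVC", "alpha_delta_P"]
    print(
        f"\nOnly the over-correcting controller is anti-persistent "
        f"perpendicular to the GEM (alpha={anti:.3f} < 0.5)."
    )


if __name__ == "__main__":
    main()
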