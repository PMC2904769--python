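"""Full single-trial analysis of a human-like (OVC-simulated) walking trial.

Generates one 272-stride trial at v = 1.21 m/s, decomposes it onto the
constant-speed GEM and reports mean/SD/DFA-alpha for the basic stride
parameters (T, L, S), the net treadmill displacement, and the GEM
deviations.  The trial reproduces the qualitative structure of human
treadmill data: persistent stride times and lengths, anti-persistent
stride speeds, variance concentrated along the GEM, and persistent
tangent vs anti-persistent perpendicular deviations.
"""

import argparse
from pathlib import Path

from gaitgem import analyze_trial, make_humanlike_trial, write_stride_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--strides", type=int, default=272)
    args = parser.parse_args()

    RESULTS.mkdir(exist_ok=True)
    trial = make_humanlike_trial(n_strides=args.strides, seed=args.seed)
    write_stride_csv(trial, RESULTS / "humanlike_trial.csv")
    summary, dev = analyze_trial(trial)
    dev.write_csv(RESULTS / "humanlike_deviations.csv")
    tidy = summary.to_tidy()
    tidy.to_csv(RESULTS / "humanlike_summary.csv", index=False, float_format="%.6g")

    print(f"trial: {trial.n_strides} strides at v = {trial.v} m/s")
    print(tidy.to_string(index=False))
    st = summary.stats
    print(
        f"\npersistence: alpha(T)={st['T'].alpha:.2f}, alpha(L)={st['L'].alpha:.2f} "
        f"(both > 0.5) but alpha(S)={st['S'].alpha:.2f} (< 0.5): stride speed is "
        "the tightly regulated variable."
    )
    print(
        f"GEM: SD(delta_T)={st['delta_T'].sd:.2f} vs SD(delta_P)={st['delta_P'].sd:.2f}; "
        f"alpha(delta_T)={st['delta_T'].alpha:.2f} vs "
        f"alpha(delta_P)={st['delta_P'].alpha:.2f}: deviations along the GEM "
        "persist, deviations off it are over-corrected."
    )
    print(
        f"belt: d_net within [{summary.min_dnet:+.3f}, {summary.max_dnet:+.3f}] m "
        "(half-belt bound is 0.864 m)."
    )


if __name__ == "__main__":
    main()
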