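#!/usr/bin/env python
"""Censored resolution-time profiles and the genotype-style contrast.

Generates a wild-type-like cohort (lognormal resolution times centred in
the tens of seconds) and a mutant-like cohort (constrictions persisting
through the 210 s capture), 29 tracks each; reduces tracks to resolved /
"never" outcomes with the 500 nm / 2-frame separation rule; bins resolved
times as [0,15], (15,60], (60,210] s plus "never"; and compares the groups
with an exact test on the resolved-vs-never counts.
"""

import argparse
import json
from pathlib import Path

from ermdquant.kinetics import compare_groups, frequency_profile, resolution_time
from ermdquant.synthetic import SimulationConfig, generate_tip_tracks


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    wt_cfg = SimulationConfig(
        seed=args.seed,
        resolution_time_distribution=("lognormal", (30.0, 0.35)),
        censor_fraction=0.0,
    )
    mu_cfg = SimulationConfig(seed=args.seed + 10_000, censor_fraction=1.0)

    wt_tracks, _ = generate_tip_tracks(wt_cfg, 29)
    mu_tracks, _ = generate_tip_tracks(mu_cfg, 29)
    wt = [resolution_time(t) for t in wt_tracks]
    mu = [resolution_time(t) for t in mu_tracks]

    bins = [0.0, 15.0, 60.0, 210.0]
    wt_profile = frequency_profile(wt, bins)
    mu_profile = frequency_profile(mu, bins)
    contrast = compare_groups(wt, mu)

    summary = {
        "bins_s": bins,
        "wild_type_like": dict(zip(wt_profile.labels(),
                                   wt_profile.counts.tolist()
                                   + [wt_profile.never])),
        "mutant_like": dict(zip(mu_profile.labels(),
                                mu_profile.counts.tolist()
                                + [mu_profile.never])),
        "resolved_fraction_difference": contrast.effect,
        "ci_95": [contrast.ci_low, contrast.ci_high],
        "fisher_p": contrast.p_value,
    }
    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "kinetics_summary.json").write_text(
        json.dumps(summary, indent=1)
    )

    print("resolution-time frequency profiles (n=29 per group)")
    for name, prof in (("wild-type-like", wt_profile), ("mutant-like", mu_profile)):
        cells = ", ".join(
            f"{lab}: {c}" for lab, c in zip(
                prof.labels(), prof.counts.tolist() + [prof.never])
        )
        print(f"  {name:15s} {cells}")
    print(f"  resolved-fraction difference: {contrast.effect:.2f} "
          f"(95% CI {contrast.ci_low:.2f}..{contrast.ci_high:.2f}), "
          f"exact p = {contrast.p_value:.2e}")


if __name__ == "__main__":
    main()
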