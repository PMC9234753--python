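#!/usr/bin/env python
"""Simulate the synthetic study cohort: 9 unassisted-style (NO_EXO, healthy
preset) and 9 assisted-style (EXO, exo_like preset) treadmill trials of
5 minutes at 100 Hz, written as marker CSVs plus a study manifest.

Trial files are large (~3 MB each), so they go under scratch/ by default;
downstream scripts read them through the manifest.

Usage: python analysis/01_simulate_cohort.py [--outdir scratch/cohort] [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from interlimb import generate_bilateral_gait, preset, write_trial


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("scratch/cohort"))
    parser.add_argument("--seed", type=int, default=1, help="first trial seed")
    parser.add_argument("--n-per-group", type=int, default=9)
    parser.add_argument("--duration", type=float, default=300.0)
    args = parser.parse_args()

    args.outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    seed = args.seed
    for group, preset_name in (("NO_EXO", "healthy"), ("EXO", "exo_like")):
        for i in range(args.n_per_group):
            cfg = preset(preset_name, seed=seed, duration_s=args.duration)
            trial, _ = generate_bilateral_gait(cfg)
            name = f"{group.lower()}_{i + 1:02d}.csv"
            write_trial(trial, args.outdir / name)
            rows.append({
                "trial_id": f"{group}{i + 1:02d}", "group": group,
                "path": name, "belt_speed": cfg.belt_speed,
            })
            print(f"  {name}: {group} preset={preset_name} seed={seed} "
                  f"({trial.n_samples} samples)")
            seed += 1

    manifest = args.outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    print(f"cohort of {len(rows)} trials written; manifest: {manifest}")


if __name__ == "__main__":
    main()
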