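#!/usr/bin/env python
"""Quantify the two theoretical coordination extremes that bracket healthy
gait: a perfectly periodic sinusoid pair (metronomic coordination — long
unbroken diagonal recurrence lines, near-zero cross sample entropy) and an
independent white-noise pair (no coordination — negligible diagonal
structure, high entropy), alongside one healthy-preset synthetic trial.

Writes results/reference_extremes.csv.

Usage: python analysis/03_reference_extremes.py [--seed 7]
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from interlimb import (
    cross_sample_entropy,
    decimate,
    generate_bilateral_gait,
    generate_random_pair,
    generate_sinusoid_pair,
    preset,
    run_crqa,
)
from interlimb.io import AnalysisConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    raw_cfg = AnalysisConfig(analysis_samples=None, decimation_factor=1)
    rows = []

    sin_a, sin_b = generate_sinusoid_pair(0.86, 0.0, 1200, 10.0)
    rnd_a, rnd_b = generate_random_pair(1200, args.seed)
    trial, _ = generate_bilateral_gait(preset("healthy", seed=args.seed))
    gait_cfg = AnalysisConfig()
    gait_a, gait_b = trial.channel("heel_L", "AP"), trial.channel("heel_R", "AP")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FNN does not converge on white noise
        for label, (a, b), cfg in (
            ("sinusoid_pair", (sin_a, sin_b), raw_cfg),
            ("healthy_gait", (gait_a, gait_b), gait_cfg),
            ("random_pair", (rnd_a, rnd_b), raw_cfg),
        ):
            crqa = run_crqa(a, b, cfg)
            da = decimate(a[: cfg.analysis_samples], cfg.decimation_factor)
            db = decimate(b[: cfg.analysis_samples], cfg.decimation_factor)
            cse = cross_sample_entropy(da, db, m=cfg.cse_m, r_factor=cfg.cse_r_factor)
            rows.append({
                "signal": label, "tau": crqa.tau, "emb": crqa.emb,
                "radius": crqa.radius, "recurrence_rate": crqa.recurrence_rate,
                "percent_determinism": crqa.percent_determinism,
                "mean_line": crqa.mean_line, "cse": cse.value,
            })
            print(f"{label:14s}: %DET {crqa.percent_determinism:6.2f}  "
                  f"MeanL {crqa.mean_line:6.2f}  cSE {cse.value:.4f}")

    args.outdir.mkdir(parents=True, exist_ok=True)
    out = args.outdir / "reference_extremes.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\nhealthy gait sits between the extremes; table written to {out}")


if __name__ == "__main__":
    main()
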