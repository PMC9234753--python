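#!/usr/bin/env python
"""Run the full per-trial pipeline over the simulated cohort and the
between-group statistics.

Per trial: heel-strike detection and first-200-step spatiotemporal
summaries at 100 Hz; then the nonlinear stage on the first 120 s of AP heel
data decimated to 10 Hz — AMI delay, FNN dimension (max across legs),
cross-recurrence at the radius calibrated to 2.5% recurrence rate, %DET and
MeanL, and cross sample entropy (m=3, r=0.25 SD).  Outcomes are assembled
into a group table and routed through Shapiro-Wilk-gated pooled t /
Mann-Whitney U tests at alpha=0.05.

Writes results/group_table.csv and results/test_results.csv and prints the
group contrast for the coordination measures.

Usage: python analysis/02_run_study.py [--manifest scratch/cohort/manifest.csv]
"""

import argparse
from pathlib import Path

from interlimb import load_manifest, results_table, run_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--manifest", type=Path, default=Path("scratch/cohort/manifest.csv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    manifest = load_manifest(args.manifest)
    table, tests, reports = run_study(manifest)

    args.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.outdir / "group_table.csv", index=False)
    df = results_table(tests)
    df.to_csv(args.outdir / "test_results.csv", index=False)

    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    by_var = {t.variable: t for t in tests}
    ml, cse = by_var["mean_line"], by_var["cse"]
    print(
        f"\ncoordination duration: MeanL EXO {ml.group_means['EXO']:.2f} vs "
        f"NO_EXO {ml.group_means['NO_EXO']:.2f} points "
        f"({ml.test}, p={ml.p_value:.4f}) — shorter under assistance-like coupling"
    )
    print(
        f"coordination synchrony: cSE EXO {cse.group_means['EXO']:.3f} vs "
        f"NO_EXO {cse.group_means['NO_EXO']:.3f} "
        f"({cse.test}, p={cse.p_value:.4f}) — more asynchronous under "
        f"assistance-like coupling"
    )
    print(f"\ntables written to {args.outdir}/group_table.csv and test_results.csv")


if __name__ == "__main__":
    main()
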