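# interlimb

Inter-limb gait coordination analysis for bilateral heel-marker
trajectories: spatiotemporal step metrics plus two nonlinear coordination
measures — **cross-recurrence quantification analysis (cRQA)** at a fixed
2.5% recurrence rate and **cross sample entropy (cSE)** — with a calibrated
synthetic treadmill-gait generator so every stage is testable and fully
reproducible without motion-capture data.

## Who this is for

Researchers in gait biomechanics and nonlinear dynamics who want to ask:
*for how long, and how tightly, do the two legs stay coordinated during
treadmill walking?* Classic spatiotemporal means (step length/time/width)
are often insensitive to interventions — e.g. walking with a passive
assistive exoskeleton — that nonetheless change the *dynamics* of
inter-limb coupling. cRQA and cSE capture those dynamics: healthy gait sits
between the metronomic extreme (two sinusoids; endless diagonal recurrence
lines) and the random extreme (white noise; no diagonal structure).

## The measures

Given left/right anterior-posterior (AP) heel trajectories sampled at
100 Hz, the pipeline takes the first 12,000 samples, decimates by 10 (no
filtering) to 1,200 points, and:

1. **Delay embedding.** Per leg, the delay τ is the first minimum of the
   average mutual information profile and the dimension *m* (EMB) is the
   smallest one at which the Kennel false-nearest-neighbor fraction drops
   below 1%. When the legs disagree, the higher value is used for the pair.
2. **Cross-recurrence plot.** R(i,j) = 1 iff ‖**x**ᵢ − **y**ⱼ‖ ≤ ρ, where
   **x**, **y** are the embedded left/right trajectories. The radius ρ is
   calibrated by bisection so the recurrence rate
   RR = 100·ΣR/(n_x·n_y) hits 2.5% (±0.05 pp).
3. **Diagonal-line statistics.** With minimum line length 2:
   %DET = 100·Σ_{l≥2} l·P(l) / ΣR (determinism of the coupling) and
   MeanL = Σ l·P(l) / Σ P(l) (mean coordination duration, in 0.1 s samples).
4. **Cross sample entropy.** With both series standardized,
   cSE = −ln(A/B), where B counts cross template pairs of length m = 3
   within Chebyshev tolerance r = 0.25 (i.e. 0.25·SD) and A the same at
   m + 1. Higher cSE = less synchrony.
5. **Statistics.** Per-participant outcomes (step metrics, EMB, radius,
   %DET, MeanL, cSE) enter Shapiro-Wilk-routed two-sample tests: pooled
   t (df = n₁+n₂−2) when both groups pass normality at α = 0.05,
   Mann-Whitney U (exact p for small groups) otherwise.

## Worked example

```python
from interlimb import preset, generate_bilateral_gait, run_trial

trial, truth = generate_bilateral_gait(preset("healthy", seed=1))
report = run_trial(trial)
c = report.crqa
print(f"tau {c.tau}  emb {c.emb}  radius {c.radius:.1f} mm  "
      f"RR {c.recurrence_rate:.3f}%")
print(f"%DET {c.percent_determinism:.2f}  MeanL {c.mean_line:.2f} points  "
      f"cSE {report.cse.value:.4f}")
print("mean step time (s):", {k: round(v, 3)
      for k, v in report.spatiotemporal.step_time_mean.items()})
```

prints

```
tau 3  emb 4  radius 57.5 mm  RR 2.500%
%DET 92.33  MeanL 10.15 points  cSE 0.1559
mean step time (s): {'L': 0.582, 'R': 0.581}
```

Read: the limb pair embeds in 4 dimensions with a 0.3 s delay; at the
radius giving exactly 2.5% recurrence, 92% of recurrent points lie on
diagonal lines averaging ~1 s (10 samples at 10 Hz) — strongly
deterministic coordination with the healthy-scale synchrony (cSE ≈ 0.16)
and a 0.58 s step time.

The same flows exist as a CLI: `interlimb simulate`, `interlimb run-trial`,
`interlimb run-study`, `interlimb stats` (see `--help`).

## The synthetic study

`analysis/` holds the numbered drivers of the full synthetic experiment:

- `01_simulate_cohort.py` — 9 + 9 five-minute trials (healthy vs
  "exo-like" preset, which only doubles the inter-limb phase-jitter SD),
  written under `scratch/cohort/` with a manifest;
- `02_run_study.py` — the per-trial pipeline and group statistics; writes
  `results/group_table.csv` and `results/test_results.csv`. On the default
  cohort the coordination contrast comes out as expected: shorter mean
  diagonal lines (6.80 vs 9.64 points) and higher cross sample entropy
  (0.167 vs 0.155) under the noisier coupling, with no meaningful change
  in step time or length and identical embedding dimension;
- `03_reference_extremes.py` — the sinusoid/random bracketing table
  (`results/reference_extremes.csv`).

## Layout

```
src/interlimb/      library (synthetic, io, spatiotemporal, embedding,
                    crqa, crossentropy, stats, pipeline, cli)
analysis/           numbered study drivers
tests/              pytest suite (unit, property, acceptance)
scripts/            acceptance.py
docs/methods.md     model and methods documentation
```
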