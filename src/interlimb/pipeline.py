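"""Trial-level and study-level orchestration.

``run_trial`` composes the whole per-participant analysis: heel-strike
detection and spatiotemporal summaries on the full-rate data, then the
nonlinear stage (truncate AP heel channels to the analysis window,
decimate, AMI/FNN embedding, radius calibration, cRQA, cross sample
entropy) on the decimated pair.  ``run_study`` maps it over a manifest and
feeds the assembled group table into the statistical stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crossentropy import CSEResult, cross_sample_entropy
from .crqa import CRQAResult, run_crqa
from .embedding import decimate
from .exceptions import InterlimbError
from .io import AnalysisConfig, StudyManifest, load_trial, log_provenance
from .spatiotemporal import SpatiotemporalSummary, spatiotemporal_summary
from .stats import TestResult, compare_groups, results_table
from .trial import GaitEvents, MarkerTrial

logger = logging.getLogger(__name__)


@dataclass
class TrialReport:
    """Complete per-trial analysis output."""

    trial_id: str
    spatiotemporal: SpatiotemporalSummary
    crqa: CRQAResult
    cse: CSEResult
    config: AnalysisConfig
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "trial_id": self.trial_id,
            "spatiotemporal": asdict(self.spatiotemporal),
            "crqa": {
                "radius": self.crqa.radius,
                "recurrence_rate": self.crqa.recurrence_rate,
                "percent_determinism": self.crqa.percent_determinism,
                "mean_line": self.crqa.mean_line,
                "line_histogram": {str(k): v for k, v in self.crqa.line_histogram.items()},
                "emb": self.crqa.emb,
                "tau": self.crqa.tau,
                "tau_L": self.crqa.params.tau_L if self.crqa.params else None,
                "tau_R": self.crqa.params.tau_R if self.crqa.params else None,
                "emb_L": self.crqa.params.emb_L if self.crqa.params else None,
                "emb_R": self.crqa.params.emb_R if self.crqa.params else None,
            },
            "cse": asdict(self.cse),
            "config": self.config.to_dict(),
            "warnings": self.warnings,
        }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _stage(name: str):
    """Decorator-ish context: re-raise stage errors with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, InterlimbError):
                exc.args = (f"[stage: {name}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
            return False
    return _Ctx()


def run_trial(trial: MarkerTrial | str | Path, config: AnalysisConfig | None = None,
              events: GaitEvents | None = None, belt_speed: float | None = None) -> TrialReport:
    """Run the full per-trial analysis.

    ``trial`` may be a loaded :class:`MarkerTrial` or a CSV path (then
    ``belt_speed`` applies).  ``events`` overrides heel-strike detection
    (e.g. ground-truth events from the synthetic generator).
    """
    cfg = config if config is not None else AnalysisConfig()
    if not isinstance(trial, MarkerTrial):
        trial = load_trial(trial, belt_speed=belt_speed or 0.0)
    log_provenance(cfg, trial=trial.trial_id)

    import warnings as _warnings

    caught: list[str] = []
    with _warnings.catch_warnings(record=True) as wlist:
        _warnings.simplefilter("always")
        with _stage("spatiotemporal"):
            st = spatiotemporal_summary(trial, events=events, n=cfg.n_steps_summary)
        with _stage("crqa"):
            crqa_result = run_crqa(trial.channel("heel_L", "AP"),
                                   trial.channel("heel_R", "AP"), cfg)
        with _stage("cross_sample_entropy"):
            ap_L = trial.channel("heel_L", "AP")[: cfg.analysis_samples]
            ap_R = trial.channel("heel_R", "AP")[: cfg.analysis_samples]
            cse_result = cross_sample_entropy(
                decimate(ap_L, cfg.decimation_factor),
                decimate(ap_R, cfg.decimation_factor),
                m=cfg.cse_m, r_factor=cfg.cse_r_factor,
            )
        caught = [str(w.message) for w in wlist]

    return TrialReport(trial_id=trial.trial_id, spatiotemporal=st,
                       crqa=crqa_result, cse=cse_result, config=cfg,
                       warnings=caught)


def group_table(reports: list[tuple[str, TrialReport]]) -> pd.DataFrame:
    """Assemble (group, report) pairs into the study's group table.

    One row per participant; columns are the tested outcomes (left/right
    spatiotemporal means, EMB, radius, %DET, MeanL, cSE).
    """
    rows = []
    for group, rep in reports:
        st = rep.spatiotemporal
        rows.append({
            "trial_id": rep.trial_id, "group": group,
            "step_length_L": st.step_length_mean["L"],
            "step_length_R": st.step_length_mean["R"],
            "step_time_L": st.step_time_mean["L"],
            "step_time_R": st.step_time_mean["R"],
            "step_width_L": st.step_width_mean["L"],
            "step_width_R": st.step_width_mean["R"],
            "emb": rep.crqa.emb, "radius": rep.crqa.radius,
            "percent_determinism": rep.crqa.percent_determinism,
            "mean_line": rep.crqa.mean_line, "cse": rep.cse.value,
        })
    return pd.DataFrame(rows)


def run_study(manifest: StudyManifest, config: AnalysisConfig | None = None,
              outdir: str | Path | None = None
              ) -> tuple[pd.DataFrame, list[TestResult], list[TrialReport]]:
    """Run every manifest trial and the between-group statistics.

    Returns (group table, test results, per-trial reports); when ``outdir``
    is given, writes TrialReport JSONs, the group table CSV and the test
    results CSV there.  Any failed trial aborts the study with a per-trial
    error message.
    """
    cfg = config if config is not None else manifest.config
    by_group = manifest.by_group()
    for label, rows in by_group.items():
        if len(rows) < 2:
            raise InterlimbError(
                f"group {label!r} has {len(rows)} participant(s); need >= 2"
            )

    reports: list[tuple[str, TrialReport]] = []
    for row in manifest.rows:
        try:
            trial = load_trial(row.path, trial_id=row.trial_id, belt_speed=row.belt_speed)
            rep = run_trial(trial, cfg)
        except InterlimbError as exc:
            raise InterlimbError(f"trial {row.trial_id!r} failed: {exc}") from exc
        reports.append((row.group, rep))

    table = group_table(reports)
    tests = compare_groups(table, alpha=cfg.alpha)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for _, rep in reports:
            rep.to_json(outdir / f"trial_{rep.trial_id}.json")
        table.to_csv(outdir / "group_table.csv", index=False)
        results_table(tests).to_csv(outdir / "test_results.csv", index=False)
        logger.info("study bundle written to %s", outdir)
    return table, tests, [rep for _, rep in reports]
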