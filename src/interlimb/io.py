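"""Reading and writing marker trials, study manifests and analysis
configuration.

On-disk trial format: plain CSV with a ``time`` column in seconds and one
column per marker/axis named ``<marker>_<AP|ML|VT>`` in mm, e.g.
``heel_L_AP``.  The manifest is a CSV with columns ``trial_id``, ``group``
(``EXO`` or ``NO_EXO``), ``path`` (relative to the manifest) and
``belt_speed`` (m/s); analysis parameters come from an optional YAML config
file whose keys are :class:`AnalysisConfig` fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, asdict
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, FormatError, GapError, SchemaError
from .trial import AXES, REQUIRED_MARKERS, MarkerTrial

logger = logging.getLogger(__name__)

GROUP_LABELS = ("EXO", "NO_EXO")

#: Maximum relative jitter tolerated in the time column before the sampling
#: is declared non-uniform.
_UNIFORMITY_RTOL = 1e-6


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters for the full pipeline, with study defaults.

    The nonlinear stage analyzes the first ``analysis_samples`` pre-decimation
    samples (120 s at 100 Hz), decimated by ``decimation_factor`` to 10 Hz.
    """

    decimation_factor: int = 10
    analysis_samples: int | None = 12000   # pre-decimation samples; None = all
    target_rr: float = 2.5                 # % recurrence rate
    rr_tol: float = 0.05                   # percentage points
    rr_max_iter: int = 60
    min_line: int = 2                      # points
    cse_m: int = 3
    cse_r_factor: float = 0.25
    n_steps_summary: int = 200
    alpha: float = 0.05
    ami_max_lag: int = 50
    ami_bins: int = 16
    fnn_rtol: float = 15.0
    fnn_atol: float = 2.0
    fnn_threshold: float = 0.01
    fnn_max_dim: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.target_rr < 100.0:
            raise ConfigurationError(f"target_rr must lie in (0, 100), got {self.target_rr}")
        if self.min_line < 2:
            raise ConfigurationError(f"min_line must be >= 2, got {self.min_line}")
        if self.cse_m < 1:
            raise ConfigurationError(f"cse_m must be >= 1, got {self.cse_m}")
        if self.cse_r_factor <= 0:
            raise ConfigurationError(f"cse_r_factor must be > 0, got {self.cse_r_factor}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.decimation_factor < 1:
            raise ConfigurationError("decimation_factor must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "AnalysisConfig":
        """Build a config from a (possibly empty) mapping, applying defaults
        and rejecting unknown keys."""
        mapping = dict(mapping or {})
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**mapping)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ManifestRow:
    trial_id: str
    group: str
    path: Path
    belt_speed: float


@dataclass
class StudyManifest:
    """Parsed study manifest plus the analysis configuration."""

    rows: list[ManifestRow]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def by_group(self) -> dict[str, list[ManifestRow]]:
        out: dict[str, list[ManifestRow]] = {g: [] for g in GROUP_LABELS}
        for row in self.rows:
            out[row.group].append(row)
        return out


def package_version() -> str:
    try:
        return version("interlimb")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def log_provenance(config: AnalysisConfig, **extra) -> None:
    """Emit a provenance record of the run configuration and software version."""
    logger.info("interlimb %s | config=%s | %s", package_version(),
                config.to_dict(), extra)


def write_trial(trial: MarkerTrial, path: str | Path) -> Path:
    """Write a trial to CSV in the documented column grammar."""
    path = Path(path)
    n = trial.n_samples
    data = {"time": np.arange(n) / trial.sample_rate}
    for marker in trial.marker_names:
        for j, axis in enumerate(AXES):
            data[f"{marker}_{axis}"] = trial.positions[marker][:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")
    return path


def load_trial(path: str | Path, trial_id: str | None = None,
               belt_speed: float = 0.0) -> MarkerTrial:
    """Load a marker trial from CSV, validating schema and sampling.

    The sampling rate is inferred from the ``time`` column and checked for
    uniformity; NaN samples are a hard error naming the first offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise SchemaError(f"{path}: missing required 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    mean_dt = float(dt.mean())
    if np.max(np.abs(dt - mean_dt)) > _UNIFORMITY_RTOL * max(mean_dt, 1.0) + 1e-12:
        raise FormatError(
            f"{path}: non-uniform sampling (max deviation "
            f"{np.max(np.abs(dt - mean_dt)):.3g} s from mean dt {mean_dt:.6g} s)"
        )
    sample_rate = 1.0 / mean_dt

    markers: dict[str, list[str]] = {}
    for col in df.columns:
        if col == "time":
            continue
        if "_" not in col or col.rsplit("_", 1)[1] not in AXES:
            raise SchemaError(
                f"{path}: column {col!r} does not follow '<marker>_<AP|ML|VT>'"
            )
        marker, axis = col.rsplit("_", 1)
        markers.setdefault(marker, []).append(axis)
    for required in REQUIRED_MARKERS:
        have = set(markers.get(required, []))
        if have != set(AXES):
            raise SchemaError(
                f"{path}: marker {required!r} must provide all of {AXES}, has {sorted(have)}"
            )

    positions = {}
    for marker in markers:
        cols = [f"{marker}_{axis}" for axis in AXES]
        arr = df[cols].to_numpy(dtype=float)
        if np.isnan(arr).any():
            row = int(np.where(np.isnan(arr).any(axis=1))[0][0])
            raise GapError(f"{path}: marker {marker!r} has a NaN sample at row {row}")
        positions[marker] = arr
    return MarkerTrial(positions=positions, sample_rate=sample_rate,
                       belt_speed=belt_speed,
                       trial_id=trial_id or path.stem)


def load_manifest(path: str | Path, config_path: str | Path | None = None) -> StudyManifest:
    """Load a study manifest CSV (plus optional YAML analysis config).

    All trial paths must resolve before the run starts; group labels are
    restricted to the two study arms and trial ids must be unique.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required_cols = {"trial_id", "group", "path", "belt_speed"}
    missing = required_cols - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: manifest missing columns {sorted(missing)}")

    rows: list[ManifestRow] = []
    seen: set[str] = set()
    for _, rec in df.iterrows():
        trial_id = str(rec["trial_id"])
        group = str(rec["group"])
        if group not in GROUP_LABELS:
            raise SchemaError(
                f"{path}: unknown group label {group!r} for trial {trial_id!r}; "
                f"allowed labels: {GROUP_LABELS}"
            )
        if trial_id in seen:
            raise SchemaError(f"{path}: duplicate trial_id {trial_id!r}")
        seen.add(trial_id)
        trial_path = (path.parent / str(rec["path"])).resolve()
        if not trial_path.exists():
            raise SchemaError(f"{path}: trial file not found: {trial_path}")
        rows.append(ManifestRow(trial_id=trial_id, group=group, path=trial_path,
                                belt_speed=float(rec["belt_speed"])))

    config_map: dict = {}
    if config_path is not None:
        with open(config_path) as fh:
            config_map = yaml.safe_load(fh) or {}
    config = AnalysisConfig.from_mapping(config_map)
    log_provenance(config, manifest=str(path), n_trials=len(rows))
    return StudyManifest(rows=rows, config=config)
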