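"""Heel-strike detection and linear (spatiotemporal) gait measures.

Definitions, per side:

* step time  — time from the contralateral heel strike to the ipsilateral
  heel strike (s);
* step length — AP distance from the contralateral heel at its previous
  strike to the striking heel at its strike, plus the belt travel
  ``belt_speed * step_time`` (m), since marker coordinates are
  body-relative on a treadmill;
* step width — absolute ML distance between the striking heel and the
  contralateral heel at its previous strike (m).

Summaries average the first 200 steps per side (all available when fewer,
with a warning).  Heel strikes are detected as local maxima of the heel AP
position relative to the sacrum — a marker-only convention; substitute
force-plate events by constructing :class:`~interlimb.trial.GaitEvents`
directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .exceptions import ConfigurationError, EventContractError, InsufficientDataError
from .trial import GaitEvents, MarkerTrial

logger = logging.getLogger(__name__)

SIDES = ("L", "R")


@dataclass
class SpatiotemporalSummary:
    """Mean/SD of step length (m), time (s) and width (m) per side."""

    step_length_mean: dict[str, float]
    step_length_sd: dict[str, float]
    step_time_mean: dict[str, float]
    step_time_sd: dict[str, float]
    step_width_mean: dict[str, float]
    step_width_sd: dict[str, float]
    n_steps_used: dict[str, int]
    warnings: list[str] = field(default_factory=list)


def _dominant_period(signal: np.ndarray, sample_rate: float) -> float:
    """Dominant period (samples) from the FFT peak, DC excluded."""
    x = signal - signal.mean()
    spectrum = np.abs(np.fft.rfft(x))
    spectrum[0] = 0.0
    k = int(np.argmax(spectrum))
    if k == 0 or spectrum[k] == 0:
        raise InsufficientDataError("no dominant oscillation found in heel trajectory")
    return len(x) / k


def detect_heel_strikes(trial: MarkerTrial, smooth_window_s: float = 0.15) -> GaitEvents:
    """Detect heel strikes as local maxima of (heel AP - sacrum AP) per side.

    A light Savitzky-Golay smoothing (for peak localization only; the raw
    data are untouched downstream) suppresses measurement noise, and a
    minimum peak separation of 0.4 median cycles rejects spurious maxima.
    Indices refer to the original sampling.
    """
    sacrum_ap = trial.channel("sacrum", "AP")
    strikes: dict[str, np.ndarray] = {}
    for side in SIDES:
        rel = trial.channel(f"heel_{side}", "AP") - sacrum_ap
        if np.ptp(rel) == 0:
            raise InsufficientDataError(
                f"heel_{side} AP relative to sacrum is constant; no strikes detectable"
            )
        window = max(5, int(round(smooth_window_s * trial.sample_rate)) | 1)
        if window < len(rel):
            rel = savgol_filter(rel, window_length=window, polyorder=2)
        period = _dominant_period(rel, trial.sample_rate)
        peaks, _ = find_peaks(rel, distance=max(1, int(round(0.4 * period))),
                              prominence=0.25 * np.ptp(rel))
        if len(peaks) < 3:
            raise InsufficientDataError(
                f"only {len(peaks)} heel strikes detected on side {side}; need >= 3"
            )
        strikes[side] = peaks
    return GaitEvents(heel_strikes_L=strikes["L"], heel_strikes_R=strikes["R"],
                      source="detected")


def _alternating_sequence(events: GaitEvents) -> tuple[np.ndarray, np.ndarray]:
    """Merged strike sequence, verified to alternate L/R."""
    idx, side = events.merged()
    if len(idx) < 2:
        raise InsufficientDataError("need at least two heel strikes to form a step")
    same = np.where(side[1:] == side[:-1])[0]
    if same.size:
        bad = ", ".join(
            f"{side[i]}@{idx[i]} followed by {side[i + 1]}@{idx[i + 1]}"
            for i in same[:5]
        )
        raise EventContractError(
            f"heel strikes do not alternate between sides at {same.size} "
            f"position(s): {bad}"
        )
    return idx, side


def step_time(events: GaitEvents, sample_rate: float) -> dict[str, np.ndarray]:
    """Per-step durations (s) per side: ipsilateral strike time minus the
    preceding contralateral strike time."""
    idx, side = _alternating_sequence(events)
    dt = np.diff(idx) / sample_rate
    landing = side[1:]
    return {s: dt[landing == s] for s in SIDES}


def step_length(events: GaitEvents, heel_ap_L: np.ndarray, heel_ap_R: np.ndarray,
                belt_speed: float, sample_rate: float) -> dict[str, np.ndarray]:
    """Per-step lengths (m) per side, belt travel included.

    Negative computed lengths are flagged, excluded and logged (they
    indicate event or marker errors, not backward walking).
    """
    if belt_speed < 0:
        raise ConfigurationError(f"belt_speed must be >= 0, got {belt_speed}")
    idx, side = _alternating_sequence(events)
    ap = {"L": np.asarray(heel_ap_L, dtype=float), "R": np.asarray(heel_ap_R, dtype=float)}
    out: dict[str, list[float]] = {s: [] for s in SIDES}
    n_flagged = 0
    for k in range(1, len(idx)):
        s, prev_s = side[k], side[k - 1]
        marker_term = (ap[s][idx[k]] - ap[prev_s][idx[k - 1]]) / 1000.0
        dt = (idx[k] - idx[k - 1]) / sample_rate
        length = marker_term + belt_speed * dt
        if length < 0:
            n_flagged += 1
            continue
        out[s].append(length)
    if n_flagged:
        msg = f"{n_flagged} step(s) with negative computed length excluded"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
    return {s: np.asarray(v) for s, v in out.items()}


def step_width(events: GaitEvents, heel_ml_L: np.ndarray,
               heel_ml_R: np.ndarray) -> dict[str, np.ndarray]:
    """Per-step widths (m) per side: |ML of striking heel at its strike -
    ML of contralateral heel at its previous strike|."""
    idx, side = _alternating_sequence(events)
    ml = {"L": np.asarray(heel_ml_L, dtype=float), "R": np.asarray(heel_ml_R, dtype=float)}
    out: dict[str, list[float]] = {s: [] for s in SIDES}
    for k in range(1, len(idx)):
        s, prev_s = side[k], side[k - 1]
        out[s].append(abs(ml[s][idx[k]] - ml[prev_s][idx[k - 1]]) / 1000.0)
    return {s: np.asarray(v) for s, v in out.items()}


def summarize_first_n(step_lengths: dict[str, np.ndarray],
                      step_times: dict[str, np.ndarray],
                      step_widths: dict[str, np.ndarray],
                      n: int = 200) -> SpatiotemporalSummary:
    """Mean/SD of the first ``min(n, available)`` steps per side.

    Emits a warning (kept in the summary) when fewer than ``n`` steps are
    available on a side.
    """
    notes: list[str] = []
    means: dict[str, dict[str, float]] = {}
    sds: dict[str, dict[str, float]] = {}
    n_used: dict[str, int] = {}
    series_by_kind = {"length": step_lengths, "time": step_times, "width": step_widths}
    for kind, per_side in series_by_kind.items():
        means[kind], sds[kind] = {}, {}
        for s in SIDES:
            values = np.asarray(per_side[s], dtype=float)
            if values.size == 0:
                raise InsufficientDataError(f"no step {kind} values on side {s}")
            used = values[: min(n, values.size)]
            if used.size < n:
                note = f"side {s}: only {used.size} step {kind} values (requested {n})"
                notes.append(note)
                warnings.warn(note, stacklevel=2)
            means[kind][s] = float(np.mean(used))
            sds[kind][s] = float(np.std(used, ddof=1)) if used.size > 1 else 0.0
            n_used[s] = min(n_used.get(s, used.size), used.size)
    return SpatiotemporalSummary(
        step_length_mean=means["length"], step_length_sd=sds["length"],
        step_time_mean=means["time"], step_time_sd=sds["time"],
        step_width_mean=means["width"], step_width_sd=sds["width"],
        n_steps_used=n_used, warnings=notes,
    )


def spatiotemporal_summary(trial: MarkerTrial, events: GaitEvents | None = None,
                           n: int = 200) -> SpatiotemporalSummary:
    """Convenience composition: detect events (unless given) and summarize."""
    if events is None:
        events = detect_heel_strikes(trial)
    times = step_time(events, trial.sample_rate)
    lengths = step_length(events, trial.channel("heel_L", "AP"),
                          trial.channel("heel_R", "AP"), trial.belt_speed,
                          trial.sample_rate)
    widths = step_width(events, trial.channel("heel_L", "ML"),
                        trial.channel("heel_R", "ML"))
    return summarize_first_n(lengths, times, widths, n=n)
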