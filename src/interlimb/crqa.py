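"""Cross-recurrence quantification between the embedded left and right heel
trajectories.

The cross-recurrence plot marks every pair of times (i, j) at which the
left-leg trajectory passes within a tolerance radius (Euclidean, closed
ball) of the right-leg trajectory.  The radius is not fixed a priori: it is
calibrated by bisection so the plot's recurrence rate hits a fixed target
(2.5% by default), making plots comparable across participants.  Diagonal
lines — runs of recurrent points with i - j constant — measure how long the
two limbs stay in the same region of state space; %DET is the fraction of
recurrent points on diagonals of at least ``min_line`` points, and MeanL
their mean length.

Cross plots have no line of identity, so no cell is excluded from the
recurrence-rate denominator.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import CalibrationError, ConfigurationError, NoLinesError
from .embedding import EmbeddingParams

logger = logging.getLogger(__name__)


@dataclass
class RecurrencePlot:
    """Binary cross-recurrence grid R(i, j) at a given radius (mm)."""

    R: np.ndarray
    radius: float

    @property
    def recurrence_rate(self) -> float:
        """Percentage of recurrent cells over all n_A * n_B cells."""
        return 100.0 * float(np.count_nonzero(self.R)) / self.R.size

    @property
    def n_recurrent(self) -> int:
        return int(np.count_nonzero(self.R))


@dataclass
class CRQAResult:
    """Quantification of one limb pair's cross-recurrence plot.

    ``radius`` is in embedded-coordinate mm; ``mean_line`` in
    post-decimation samples (0.1 s each at the default 10 Hz).
    """

    radius: float
    recurrence_rate: float
    percent_determinism: float
    mean_line: float
    line_histogram: dict[int, int]
    emb: int
    tau: int
    params: EmbeddingParams | None = None
    n_points: tuple[int, int] = (0, 0)


def cross_recurrence(trajA: np.ndarray, trajB: np.ndarray, radius: float) -> RecurrencePlot:
    """Threshold the Euclidean cross-distance grid at ``radius`` (closed ball)."""
    trajA = np.atleast_2d(np.asarray(trajA, dtype=float))
    trajB = np.atleast_2d(np.asarray(trajB, dtype=float))
    if trajA.shape[1] != trajB.shape[1]:
        raise ConfigurationError(
            f"embedding dimensions differ: {trajA.shape[1]} vs {trajB.shape[1]}"
        )
    if radius <= 0:
        raise ConfigurationError(f"radius must be positive, got {radius}")
    D = cdist(trajA, trajB)
    return RecurrencePlot(R=D <= radius, radius=float(radius))


def calibrate_radius(trajA: np.ndarray, trajB: np.ndarray, target_rr: float = 2.5,
                     tol: float = 0.05, max_iter: int = 60) -> tuple[float, float]:
    """Bisection for the smallest radius whose recurrence rate is within
    ``tol`` percentage points of ``target_rr`` (%).

    Exploits monotonicity of RR in the radius.  Returns
    ``(radius, achieved_rr)``.  Raises :class:`CalibrationError` (reporting
    the final bracket) when no radius satisfies the tolerance — possible
    with heavily tied distances on tiny trajectories.
    """
    if not 0.0 < target_rr <= 100.0:
        raise ConfigurationError(f"target_rr must lie in (0, 100], got {target_rr}")
    trajA = np.atleast_2d(np.asarray(trajA, dtype=float))
    trajB = np.atleast_2d(np.asarray(trajB, dtype=float))
    if trajA.shape[1] != trajB.shape[1]:
        raise ConfigurationError(
            f"embedding dimensions differ: {trajA.shape[1]} vs {trajB.shape[1]}"
        )
    D = cdist(trajA, trajB)
    n_cells = D.size

    def rr(radius: float) -> float:
        return 100.0 * float(np.count_nonzero(D <= radius)) / n_cells

    hi = float(D.max())
    rr_hi = rr(hi)
    if rr_hi <= target_rr:  # target at/above 100% of cells
        if abs(rr_hi - target_rr) <= tol:
            return hi, rr_hi
        raise CalibrationError(
            f"even the maximum distance {hi:.6g} gives RR {rr_hi:.4f}% < target"
        )

    # Bisect to convergence, keeping the radius whose RR is closest to the
    # target (ties broken toward the smaller radius).  RR is a step function
    # of the radius, so the bracket shrinks onto the distance quantile that
    # best realizes the target rate.
    lo = 0.0
    best_radius, best_rr = hi, rr_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = rr(mid)
        if abs(r_mid - target_rr) < abs(best_rr - target_rr) or (
            abs(r_mid - target_rr) == abs(best_rr - target_rr) and mid < best_radius
        ):
            best_radius, best_rr = mid, r_mid
        if r_mid < target_rr:
            lo = mid
        else:
            hi = mid
    if abs(best_rr - target_rr) > tol:
        raise CalibrationError(
            f"bisection did not reach RR {target_rr}% +/- {tol} pp in {max_iter} "
            f"iterations; best RR {best_rr:.4f}% at radius {best_radius:.6g}, "
            f"final bracket [{lo:.6g}, {hi:.6g}] (distance ties too coarse?)"
        )
    return best_radius, best_rr


def diagonal_histogram(plot: RecurrencePlot, min_line: int = 2) -> dict[int, int]:
    """Counts of maximal diagonal runs (i - j constant) of length >= min_line.

    Runs touching the plot border are counted at their observed length.
    """
    if min_line < 1:
        raise ConfigurationError(f"min_line must be >= 1, got {min_line}")
    R = plot.R
    n_a, n_b = R.shape
    counts: Counter[int] = Counter()
    for offset in range(-(n_a - 1), n_b):
        diag = np.diagonal(R, offset=offset)
        if not diag.any():
            continue
        # run lengths via edges of the padded boolean sequence
        padded = np.concatenate(([False], diag, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        lengths = edges[1::2] - edges[0::2]
        for length in lengths:
            if length >= min_line:
                counts[int(length)] += 1
    return dict(sorted(counts.items()))


def percent_determinism(histogram: dict[int, int], plot: RecurrencePlot) -> float:
    """Percentage of recurrent points lying on diagonal lines."""
    total = plot.n_recurrent
    if total == 0:
        raise NoLinesError("recurrence plot has no recurrent points; %DET undefined")
    on_lines = sum(length * count for length, count in histogram.items())
    return 100.0 * on_lines / total


def mean_line(histogram: dict[int, int]) -> float:
    """Mean diagonal-line length (points) over lines of at least min_line."""
    n_lines = sum(histogram.values())
    if n_lines == 0:
        raise NoLinesError("no diagonal lines of the minimum length; MeanL undefined")
    return sum(length * count for length, count in histogram.items()) / n_lines


def run_crqa(series_L: np.ndarray, series_R: np.ndarray, config=None) -> CRQAResult:
    """Full cRQA pipeline on a pair of same-rate AP heel series.

    Stages: truncate to the configured analysis window, decimate, per-leg
    AMI delay and FNN dimension, combine (max across legs), delay-embed
    both legs, calibrate the radius to the target recurrence rate, then
    quantify the diagonal-line structure.

    ``config`` is an :class:`~interlimb.io.AnalysisConfig`; defaults are
    used when omitted.
    """
    from .io import AnalysisConfig  # local import to avoid a cycle

    cfg = config if config is not None else AnalysisConfig()
    series_L = np.asarray(series_L, dtype=float)
    series_R = np.asarray(series_R, dtype=float)
    if series_L.shape != series_R.shape:
        raise ConfigurationError(
            f"left/right series lengths differ: {series_L.shape} vs {series_R.shape}"
        )

    from .embedding import decimate, embed, fnn_dimension, pair_params, select_delay

    if cfg.analysis_samples is not None:
        series_L = series_L[: cfg.analysis_samples]
        series_R = series_R[: cfg.analysis_samples]
    dec_L = decimate(series_L, cfg.decimation_factor)
    dec_R = decimate(series_R, cfg.decimation_factor)

    tau_L = select_delay(dec_L, max_lag=cfg.ami_max_lag, bins=cfg.ami_bins)
    tau_R = select_delay(dec_R, max_lag=cfg.ami_max_lag, bins=cfg.ami_bins)
    emb_L = fnn_dimension(dec_L, tau_L, max_dim=cfg.fnn_max_dim, rtol=cfg.fnn_rtol,
                          atol=cfg.fnn_atol, threshold=cfg.fnn_threshold)
    emb_R = fnn_dimension(dec_R, tau_R, max_dim=cfg.fnn_max_dim, rtol=cfg.fnn_rtol,
                          atol=cfg.fnn_atol, threshold=cfg.fnn_threshold)
    params = pair_params(tau_L, tau_R, emb_L, emb_R,
                         decimation_factor=cfg.decimation_factor)
    logger.info("embedding: tau=%d (L=%d R=%d), emb=%d (L=%d R=%d)",
                params.tau, tau_L, tau_R, params.emb, emb_L, emb_R)

    traj_L = embed(dec_L, params)
    traj_R = embed(dec_R, params)
    radius, achieved_rr = calibrate_radius(traj_L, traj_R, target_rr=cfg.target_rr,
                                           tol=cfg.rr_tol, max_iter=cfg.rr_max_iter)
    plot = cross_recurrence(traj_L, traj_R, radius)
    hist = diagonal_histogram(plot, min_line=cfg.min_line)
    det = percent_determinism(hist, plot)
    ml = mean_line(hist)
    logger.info("cRQA: radius=%.3f RR=%.3f%% %%DET=%.2f MeanL=%.3f",
                radius, achieved_rr, det, ml)
    return CRQAResult(
        radius=radius, recurrence_rate=achieved_rr, percent_determinism=det,
        mean_line=ml, line_histogram=hist, emb=params.emb, tau=params.tau,
        params=params, n_points=(traj_L.shape[0], traj_R.shape[0]),
    )
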