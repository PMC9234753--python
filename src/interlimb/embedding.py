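"""State-space reconstruction: decimation, delay selection by average
mutual information (AMI), dimension selection by false nearest neighbors
(FNN), and delay embedding.

The analysis convention follows common practice for treadmill gait: the
100 Hz AP heel trace is truncated to the first 12,000 samples and decimated
by plain stride sampling (no anti-alias filter; the raw data enter the
nonlinear analysis unfiltered) to 10 Hz, the delay tau is the first local
minimum of the AMI profile, and the embedding dimension is the smallest one
at which the false-neighbor fraction (Kennel criteria) drops below 1%.
When the two legs disagree, the higher value of each parameter is used for
the pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ConfigurationError, DegenerateInputError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters for a limb pair, with per-leg provenance.

    ``tau`` (samples, post-decimation) and ``emb`` are the pair values:
    the maximum across legs.
    """

    tau: int
    emb: int
    tau_L: int | None = None
    tau_R: int | None = None
    emb_L: int | None = None
    emb_R: int | None = None
    decimation_factor: int = 1

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ConfigurationError(f"tau must be >= 1, got {self.tau}")
        if self.emb < 1:
            raise ConfigurationError(f"emb must be >= 1, got {self.emb}")


def decimate(series: np.ndarray, factor: int = 10) -> np.ndarray:
    """Keep every ``factor``-th sample starting at index 0 (no filtering).

    Output length is ``floor(len(series) / factor)``.
    """
    series = np.asarray(series, dtype=float)
    if factor < 1 or int(factor) != factor:
        raise ConfigurationError(f"decimation factor must be a positive integer, got {factor}")
    factor = int(factor)
    n = len(series)
    if factor > n:
        raise InsufficientDataError(f"decimation factor {factor} exceeds series length {n}")
    return series[: (n // factor) * factor : factor].copy()


def _equiprobable_bins(series: np.ndarray, bins: int) -> np.ndarray:
    """Assign each sample to one of ``bins`` equal-occupancy rank bins."""
    n = len(series)
    order = np.argsort(series, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * bins) // n


def ami_profile(series: np.ndarray, max_lag: int = 50, bins: int = 16) -> np.ndarray:
    """Average mutual information (nats) of the series against its lagged
    copy, for lags 0..max_lag, from an equal-occupancy joint histogram.

    Equiprobable bins keep the estimate stable on the strongly non-Gaussian
    amplitude distribution of cyclic gait signals.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if bins < 2:
        raise ConfigurationError(f"bins must be >= 2, got {bins}")
    if max_lag >= n / 2:
        raise ConfigurationError(f"max_lag {max_lag} must be below half the length {n}")
    if np.ptp(series) == 0:
        raise DegenerateInputError("constant series has zero entropy; AMI undefined")

    labels = _equiprobable_bins(series, bins)
    mi = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = labels[: n - lag] if lag else labels
        b = labels[lag:] if lag else labels
        joint = np.bincount(a * bins + b, minlength=bins * bins).astype(float)
        joint = joint.reshape(bins, bins)
        total = joint.sum()
        pij = joint / total
        pi = pij.sum(axis=1, keepdims=True)
        qj = pij.sum(axis=0, keepdims=True)
        mask = pij > 0
        mi[lag] = float(np.sum(pij[mask] * np.log(pij[mask] / (pi @ qj)[mask])))
    return mi


def first_minimum(profile: np.ndarray) -> int:
    """First interior local minimum of an AMI profile; the delay tau.

    Falls back to the global minimum over positive lags (with a warning)
    when no interior minimum exists.
    """
    profile = np.asarray(profile, dtype=float)
    for k in range(1, len(profile) - 1):
        if profile[k] < profile[k - 1] and profile[k] < profile[k + 1]:
            return k
    tau = int(np.argmin(profile[1:]) + 1)
    msg = f"AMI profile has no interior minimum; using global minimum at lag {tau}"
    warnings.warn(msg, stacklevel=2)
    logger.warning(msg)
    return tau


def select_delay(series: np.ndarray, max_lag: int = 50, bins: int = 16) -> int:
    """Delay tau = first minimum of the AMI profile."""
    return first_minimum(ami_profile(series, max_lag=max_lag, bins=bins))


def _delay_matrix(series: np.ndarray, tau: int, dim: int, n_points: int) -> np.ndarray:
    cols = [series[k * tau : k * tau + n_points] for k in range(dim)]
    return np.column_stack(cols)


def fnn_fractions(series: np.ndarray, tau: int, max_dim: int = 10,
                  rtol: float = 15.0, atol: float = 2.0) -> np.ndarray:
    """False-nearest-neighbor fraction at each dimension 1..max_dim.

    A neighbor pair at dimension d is false (Kennel criteria) when adding
    the (d+1)-th delay coordinate grows the distance by more than ``rtol``
    relative to the d-dimensional separation, or moves the pair apart by
    more than ``atol`` attractor sizes.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if tau < 1:
        raise ConfigurationError(f"tau must be >= 1, got {tau}")
    if tau * max_dim >= n:
        raise InsufficientDataError(
            f"series of length {n} cannot be embedded at dimension {max_dim + 1} "
            f"with tau {tau}"
        )
    attractor_size = float(np.std(series))
    if attractor_size == 0:
        raise DegenerateInputError("constant series; FNN undefined")

    fractions = np.empty(max_dim)
    for d in range(1, max_dim + 1):
        n_pts = n - d * tau  # leaves the (d+1)-th coordinate available
        if n_pts < 2:
            raise InsufficientDataError(
                f"too few points ({n_pts}) to test dimension {d} with tau {tau}"
            )
        Y = _delay_matrix(series, tau, d, n_pts)
        D = cdist(Y, Y)
        np.fill_diagonal(D, np.inf)
        nn = np.argmin(D, axis=1)
        r_d = D[np.arange(n_pts), nn]
        ext = np.abs(series[np.arange(n_pts) + d * tau] - series[nn + d * tau])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(r_d > 0, ext / np.where(r_d > 0, r_d, 1.0), np.inf)
        ratio[(r_d == 0) & (ext == 0)] = 0.0
        grown = np.sqrt(r_d**2 + ext**2) / attractor_size
        false = (ratio > rtol) | (grown > atol)
        fractions[d - 1] = float(np.mean(false))
    return fractions


def fnn_dimension(series: np.ndarray, tau: int, max_dim: int = 10,
                  rtol: float = 15.0, atol: float = 2.0,
                  threshold: float = 0.01) -> int:
    """Smallest dimension at which the false-neighbor fraction drops below
    ``threshold``; returns ``max_dim`` with a warning if it never does."""
    fractions = fnn_fractions(series, tau, max_dim=max_dim, rtol=rtol, atol=atol)
    below = np.where(fractions < threshold)[0]
    if below.size:
        return int(below[0] + 1)
    msg = (
        f"false-neighbor fraction never fell below {threshold:.2%} "
        f"(minimum {fractions.min():.2%}); returning max_dim {max_dim}"
    )
    warnings.warn(msg, stacklevel=2)
    logger.warning(msg)
    return max_dim


def pair_params(tau_L: int, tau_R: int, emb_L: int, emb_R: int,
                decimation_factor: int = 1) -> EmbeddingParams:
    """Combine per-leg parameters: the higher value of each is used for the
    pair, and the per-leg values are retained for reporting."""
    for name, v in (("tau_L", tau_L), ("tau_R", tau_R), ("emb_L", emb_L), ("emb_R", emb_R)):
        if v < 1:
            raise ConfigurationError(f"{name} must be >= 1, got {v}")
    return EmbeddingParams(
        tau=max(tau_L, tau_R), emb=max(emb_L, emb_R),
        tau_L=tau_L, tau_R=tau_R, emb_L=emb_L, emb_R=emb_R,
        decimation_factor=decimation_factor,
    )


def embed(series: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """Delay-embed a series: point i = (x_i, x_{i+tau}, ..., x_{i+(emb-1)tau}).

    Returns an ``(n - (emb-1)*tau, emb)`` array.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    span = (params.emb - 1) * params.tau
    if n <= span:
        raise InsufficientDataError(
            f"series of length {n} is too short to embed with emb={params.emb}, "
            f"tau={params.tau}; need at least {span + 1} samples"
        )
    if not np.all(np.isfinite(series)):
        raise DegenerateInputError("series contains non-finite values")
    return _delay_matrix(series, params.tau, params.emb, n - span)
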