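"""Cross sample entropy (cSE) between two equal-length series.

cSE measures the (a)synchrony of two signals: it is the negative log of
the conditional probability that two templates — one drawn from each
series — that match over m consecutive points still match over m+1.
Larger values mean patterns in one series are less likely to recur in the
other, i.e. more asynchrony.

Conventions follow the Richman-Moorman sample-entropy family: each series
is standardized to zero mean and unit SD, so the tolerance r is a fraction
of each series' own standard deviation (0.25 by default); templates match
when their Chebyshev (max-coordinate) distance is strictly below r; the
logarithm is natural.  Self-matches cannot arise in the cross comparison,
so no exclusion is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError, NoMatchesError


@dataclass(frozen=True)
class CSEResult:
    """Cross sample entropy with its match counts.

    ``value`` = -ln(matches_m1 / matches_m), natural-log units.
    """

    value: float
    m: int
    r_factor: float
    n: int
    matches_m: int
    matches_m1: int


def _chebyshev_match_count(a: np.ndarray, b: np.ndarray, m: int, r: float,
                           n_templates: int) -> int:
    """Count cross pairs (i, j) over the first ``n_templates`` start indices
    whose length-m templates match under Chebyshev distance < r."""
    D = np.abs(np.subtract.outer(a[:n_templates], b[:n_templates]))
    for k in range(1, m):
        np.maximum(D, np.abs(np.subtract.outer(a[k : k + n_templates],
                                               b[k : k + n_templates])), out=D)
    return int(np.count_nonzero(D < r))


def cross_sample_entropy(series_a: np.ndarray, series_b: np.ndarray,
                         m: int = 3, r_factor: float = 0.25) -> CSEResult:
    """Cross sample entropy of two equal-length series.

    Both series are standardized, so ``r_factor`` is the tolerance in units
    of each series' SD.  Both template lengths use the same ``n - m`` start
    indices, making -ln(A/B) a genuine conditional probability.

    Raises :class:`NoMatchesError` when no templates match at either
    length — raise ``r_factor`` or supply longer series.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError(
            f"series must be 1-D and equal length, got {a.shape} and {b.shape}"
        )
    if m < 1:
        raise ConfigurationError(f"template length m must be >= 1, got {m}")
    if r_factor <= 0:
        raise ConfigurationError(f"r_factor must be positive, got {r_factor}")
    n = len(a)
    if n < m + 2:
        raise ConfigurationError(f"need at least m + 2 = {m + 2} samples, got {n}")
    sd_a, sd_b = float(np.std(a)), float(np.std(b))
    if sd_a == 0 or sd_b == 0:
        raise DegenerateInputError("constant series; cross sample entropy undefined")
    a = (a - a.mean()) / sd_a
    b = (b - b.mean()) / sd_b

    n_templates = n - m  # same start-index range for lengths m and m+1
    B = _chebyshev_match_count(a, b, m, r_factor, n_templates)
    A = _chebyshev_match_count(a, b, m + 1, r_factor, n_templates)
    if B == 0 or A == 0:
        raise NoMatchesError(
            f"no cross template matches at m={m} (B={B}) or m+1 (A={A}) with "
            f"r={r_factor}; raise r_factor or provide longer series"
        )
    return CSEResult(value=float(-np.log(A / B)), m=m, r_factor=r_factor, n=n,
                     matches_m=B, matches_m1=A)
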