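"""Group-level statistics: Shapiro-Wilk normality routing into pooled
two-sample t-tests or Mann-Whitney U tests at alpha = 0.05.

Each outcome column of the group table is tested for normality within each
group; if either group fails at alpha, the variable is compared with a
Mann-Whitney U test (exact p for small samples), otherwise with a classic
pooled-variance independent t-test (df = n1 + n2 - 2).  Tests are two-sided
and no multiple-testing correction is applied; report consumers should
treat p-values as per-variable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, DegenerateInputError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Outcome columns of a full study group table, in report order.
OUTCOME_COLUMNS = (
    "step_length_L", "step_length_R", "step_time_L", "step_time_R",
    "step_width_L", "step_width_R", "emb", "radius",
    "percent_determinism", "mean_line", "cse",
)


@dataclass
class TestResult:
    """One between-group comparison."""

    variable: str
    test: str                    # "t" or "mann_whitney"
    statistic: float
    p_value: float
    df: int | None = None        # t only
    group_means: dict[str, float] = field(default_factory=dict)
    group_sds: dict[str, float] = field(default_factory=dict)
    group_ns: dict[str, int] = field(default_factory=dict)
    alpha: float = 0.05
    shapiro_p: dict[str, float] = field(default_factory=dict)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise InsufficientDataError(f"Shapiro-Wilk needs n >= 3, got {len(values)}")
    if len(values) > 5000:
        raise InsufficientDataError("Shapiro-Wilk p-values are unreliable beyond n = 5000")
    if np.ptp(values) == 0:
        raise DegenerateInputError("identical values; normality test undefined")
    w, p = sps.shapiro(values)
    return float(w), float(p)


def t_from_summary(mean1: float, sd1: float, n1: int,
                   mean2: float, sd2: float, n2: int) -> tuple[float, int]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, df) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ConfigurationError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateInputError("both groups have zero variance; t undefined")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    return (mean1 - mean2) / se, df


def pooled_t_test(group_a, group_b, variable: str = "", alpha: float = 0.05) -> TestResult:
    """Classic pooled-variance independent two-sample t-test (two-sided)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateInputError("zero pooled variance; t-test undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    return TestResult(
        variable=variable, test="t", statistic=float(t), p_value=float(p), df=df,
        group_means={"A": float(a.mean()), "B": float(b.mean())},
        group_sds={"A": float(a.std(ddof=1)), "B": float(b.std(ddof=1))},
        group_ns={"A": len(a), "B": len(b)}, alpha=alpha,
    )


def mann_whitney_u(group_a, group_b, variable: str = "", alpha: float = 0.05,
                   exact_max_n: int = 12) -> TestResult:
    """Mann-Whitney U test, min(U1, U2) convention, two-sided.

    Exact p-value (full null enumeration) when both groups have at most
    ``exact_max_n`` observations and no cross-group ties; the normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise InsufficientDataError("need n >= 1 per group")
    small = len(a) <= exact_max_n and len(b) <= exact_max_n
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if small and not has_ties else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, len(a) * len(b) - u1)
    return TestResult(
        variable=variable, test="mann_whitney", statistic=u,
        p_value=float(min(res.pvalue, 1.0)), df=None,
        group_means={"A": float(a.mean()), "B": float(b.mean())},
        group_sds={"A": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                   "B": float(b.std(ddof=1)) if len(b) > 1 else 0.0},
        group_ns={"A": len(a), "B": len(b)}, alpha=alpha,
    )


def compare_groups(table: pd.DataFrame, alpha: float = 0.05,
                   columns: tuple[str, ...] | None = None,
                   group_column: str = "group") -> list[TestResult]:
    """Route each outcome column through normality-dependent testing.

    Within each group, a Shapiro-Wilk test at ``alpha`` decides the route:
    any failure (or a degenerate constant group, which cannot be normal
    data) sends the variable to Mann-Whitney U; otherwise a pooled t-test.
    The routing decision is logged per variable.
    """
    groups = sorted(table[group_column].unique())
    if len(groups) != 2:
        raise ConfigurationError(f"need exactly two group labels, got {groups}")
    if columns is None:
        columns = tuple(c for c in OUTCOME_COLUMNS if c in table.columns)
    results: list[TestResult] = []
    for col in columns:
        if table[col].isna().any():
            raise ConfigurationError(f"column {col!r} has missing cells")
        a = table.loc[table[group_column] == groups[0], col].to_numpy(dtype=float)
        b = table.loc[table[group_column] == groups[1], col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise InsufficientDataError(
                f"column {col!r}: need at least 2 participants per group"
            )
        shapiro_p: dict[str, float] = {}
        normal = True
        for label, values in ((groups[0], a), (groups[1], b)):
            try:
                _, p = shapiro_wilk(values)
            except DegenerateInputError:
                p = 0.0  # constant group: cannot be treated as normal data
            shapiro_p[label] = p
            normal = normal and p >= alpha
        if normal:
            result = pooled_t_test(a, b, variable=col, alpha=alpha)
        else:
            result = mann_whitney_u(a, b, variable=col, alpha=alpha)
        result.shapiro_p = shapiro_p
        result.group_means = {groups[0]: result.group_means["A"], groups[1]: result.group_means["B"]}
        result.group_sds = {groups[0]: result.group_sds["A"], groups[1]: result.group_sds["B"]}
        result.group_ns = {groups[0]: result.group_ns["A"], groups[1]: result.group_ns["B"]}
        logger.info("variable %s routed to %s (Shapiro p: %s)", col, result.test,
                    {k: round(v, 4) for k, v in shapiro_p.items()})
        results.append(result)
    return results


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """Flatten TestResults into a tidy DataFrame (one row per variable)."""
    rows = []
    for r in results:
        groups = list(r.group_means)
        rows.append({
            "variable": r.variable, "test": r.test, "statistic": r.statistic,
            "df": r.df if r.df is not None else np.nan, "p_value": r.p_value,
            **{f"mean_{g}": r.group_means[g] for g in groups},
            **{f"sd_{g}": r.group_sds[g] for g in groups},
            **{f"n_{g}": r.group_ns[g] for g in groups},
            **{f"shapiro_p_{g}": r.shapiro_p.get(g, np.nan) for g in groups},
            "significant": r.p_value < r.alpha,
        })
    return pd.DataFrame(rows)
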