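"""Demographic-table statistics: medians/IQRs, crosstabs and group tests.

The comparison tests are implemented from first principles (exact
Mann-Whitney enumeration for small samples, hypergeometric Fisher test,
Pearson chi-squared) so that their behaviour is fully specified and
independently checkable against library implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "median_iqr",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "chi_squared_2xk",
    "crosstab_percentages",
    "compare_groups",
]

EXACT_MW_LIMIT = 12  # total sample size up to which the exact null is enumerated


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    summary: dict
    test: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) using linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr: empty input")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # U = #{(i,j): x_i > y_j} + 0.5 * #ties
    gt = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U (x vs y) with a two-sided p-value.

    With ``method="auto"`` the p-value is exact (full enumeration of group
    assignments, correct under ties) when ``len(x) + len(y) <= 12``;
    otherwise a normal approximation with tie and continuity corrections is
    used.  ``method="exact"`` / ``method="normal"`` force one route.
    Two-sided p doubles the smaller one-sided tail, capped at 1.
    """
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u: both groups must be non-empty")
    nx, ny = x.size, y.size
    u = _u_statistic(x, y)

    use_exact = method == "exact" or (method == "auto" and nx + ny <= EXACT_MW_LIMIT)
    if use_exact:
        pooled = np.concatenate([x, y])
        n = nx + ny
        # pairwise win/tie matrix: U of any assignment is a submatrix sum
        m = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
        np.fill_diagonal(m, 0.0)
        full = np.arange(n)
        us = np.asarray(
            [
                m[np.ix_(idx, np.setdiff1d(full, idx, assume_unique=True))].sum()
                for idx in combinations(range(n), nx)
            ]
        )
        total = len(us)
        eps = 1e-9
        p_low = np.sum(us <= u + eps) / total
        p_high = np.sum(us >= u - eps) / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return u, float(p)

    n = nx + ny
    mean = nx * ny / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # all values tied
        return u, 1.0
    sd = math.sqrt(var)
    # continuity-corrected tails
    p_high = sps.norm.sf((u - 0.5 - mean) / sd)
    p_low = sps.norm.cdf((u + 0.5 - mean) / sd)
    return u, float(min(1.0, 2.0 * min(p_low, p_high)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities (margins fixed) of all tables whose
    probability does not exceed the observed table's.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2: expected a 2x2 table")
    a, b, c, d = (int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
    if min(a, b, c, d) < 0:
        raise ValueError("fisher_exact_2x2: counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def pmf(k: int) -> float:
        return (
            math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)
        )

    p_obs = pmf(a)
    cutoff = p_obs * (1.0 + 1e-7)  # scipy-style relative tolerance
    return float(min(1.0, sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= cutoff)))


def chi_squared_2xk(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test on a 2xk table, df = k-1, no Yates by default."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise ValueError("chi_squared_2xk: expected a 2xk table with k >= 2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("chi_squared_2xk: zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    df = obs.shape[1] - 1
    return stat, float(sps.chi2.sf(stat, df))


def crosstab_percentages(flag, infected) -> dict:
    """Counts and percentages of infected/non-infected among flagged patients.

    Percentages are rounded to one decimal; undefined (None) when no patient
    carries the flag.
    """
    flag = np.asarray(flag, dtype=bool)
    inf = np.asarray(infected, dtype=bool)
    if flag.shape != inf.shape:
        raise ValueError("crosstab_percentages: columns must have equal length")
    total = int(flag.sum())
    n_inf = int((flag & inf).sum())
    n_non = total - n_inf
    if total == 0:
        return {
            "total": 0, "infected": 0, "non_infected": 0,
            "pct_infected": None, "pct_non_infected": None,
        }
    return {
        "total": total,
        "infected": n_inf,
        "non_infected": n_non,
        "pct_infected": round(100.0 * n_inf / total, 1),
        "pct_non_infected": round(100.0 * n_non / total, 1),
    }


def compare_groups(frame, numeric=None, categorical=None) -> list[GroupComparison]:
    """Demographics-table comparison of infected vs non-infected patients.

    Numeric variables get per-class median (IQR) and a Mann-Whitney test;
    binary/categorical variables get counts and Fisher's exact test for
    small tables (any expected count < 5) or chi-squared otherwise.  The
    chosen test is recorded in each row.
    """
    inf = frame["infected"].to_numpy(dtype=bool)
    out: list[GroupComparison] = []
    for var in numeric or []:
        vals = frame[var].to_numpy(dtype=float)
        u, p = mann_whitney_u(vals[inf], vals[~inf])
        out.append(
            GroupComparison(
                variable=var,
                summary={
                    "infected": median_iqr(vals[inf]),
                    "non_infected": median_iqr(vals[~inf]),
                },
                test="mann-whitney",
                statistic=u,
                p_value=p,
            )
        )
    for var in categorical or []:
        col = frame[var]
        levels = sorted(col.astype(str).unique())
        table = np.array(
            [[int(((col.astype(str) == lv) & ~inf).sum()) for lv in levels],
             [int(((col.astype(str) == lv) & inf).sum()) for lv in levels]]
        )
        expected_small = _expected_min(table) < 5
        if table.shape[1] == 2 and expected_small:
            p = fisher_exact_2x2(table)
            stat = float("nan")
            test = "fisher"
        else:
            stat, p = chi_squared_2xk(table)
            test = "chi-squared"
        out.append(
            GroupComparison(
                variable=var,
                summary={"levels": levels, "counts": table.tolist()},
                test=test,
                statistic=stat,
                p_value=p,
            )
        )
    return out


def _expected_min(table: np.ndarray) -> float:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    return float((row * col / table.sum()).min())
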