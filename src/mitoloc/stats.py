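"""Condition-level statistics: mean +/- SEM, Mann-Whitney, expression correlation.

The Mann-Whitney U statistic is ``#{(i,j): a_i > b_j} + 0.5 * #ties``.
For tie-free samples with small combined size the two-sided p-value is
exact, computed from the full null distribution of U (dynamic-programming
count over rank subsets); otherwise a tie-corrected normal approximation
with continuity correction is used. Two-sided p = min(1, 2 * one-sided).
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import List, Sequence

import numpy as np
from scipy import stats as sps

from .containers import CellRecord, ConditionSummary, ExpressionCorrelation, GroupComparison
from .errors import EmptyConditionError, MitolocError


def _defined_pccs(records: Sequence[CellRecord]) -> List[float]:
    return [r.pcc for r in records if not r.is_excluded]


def summarize_condition(
    records: Sequence[CellRecord], condition: str | None = None
) -> ConditionSummary:
    """Mean and SEM of per-cell PCCs over non-excluded records.

    SEM uses the sample standard deviation (n-1 denominator) and is NaN for
    a single cell. All excluded → :class:`EmptyConditionError`.
    """
    if condition is None:
        condition = records[0].condition if records else "?"
    values = _defined_pccs(records)
    if not values:
        raise EmptyConditionError(condition, "all records excluded or empty input")
    arr = np.asarray(values, dtype=float)
    n = arr.size
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
    return ConditionSummary(
        condition=condition,
        n_cells=int(n),
        mean_pcc=float(arr.mean()),
        sem_pcc=sem,
        values=[float(v) for v in arr],
    )


@lru_cache(maxsize=None)
def _u_null_counts(m: int, n: int) -> tuple:
    """Counts of rank subsets of {1..m+n} of size m achieving each U value.

    Recurrence over whether the largest rank belongs to the first group:
    c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u).
    """
    if m == 0 or n == 0:
        return (1,)
    with_last = _u_null_counts(m - 1, n)  # largest rank in group A: adds n wins
    without = _u_null_counts(m, n - 1)
    size = m * n + 1
    out = [0] * size
    for u, c in enumerate(with_last):
        out[u + n] += c
    for u, c in enumerate(without):
        out[u] += c
    return tuple(out)


def exact_u_pvalue(u: float, m: int, n: int) -> float:
    """Exact two-sided p for a tie-free U observation."""
    counts = np.asarray(_u_null_counts(m, n), dtype=float)
    total = counts.sum()
    u_low = min(u, m * n - u)
    p_one = counts[: int(math.floor(u_low + 1e-9)) + 1].sum() / total
    return min(1.0, 2.0 * p_one)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], *, exact_max_total: int = 16
) -> GroupComparison:
    """Two-sided Mann-Whitney comparison of two value lists."""
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if av.size == 0 or bv.size == 0:
        raise MitolocError("both groups must be nonempty")
    m, n = av.size, bv.size

    combined = np.concatenate([av, bv])
    ranks = sps.rankdata(combined)  # average ranks handle ties as half-wins
    r_a = ranks[:m].sum()
    u = float(r_a - m * (m + 1) / 2)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and (m + n) <= exact_max_total:
        p = exact_u_pvalue(u, m, n)
        method = "exact"
    else:
        method = "normal_tie_corrected"
        big_n = m + n
        mean_u = m * n / 2.0
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1)))
        var_u = m * n / 12.0 * ((big_n + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            diff = u - mean_u
            cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
            z = (diff - cc) / math.sqrt(var_u)
            p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return GroupComparison(
        condition_a="a",
        condition_b="b",
        u_statistic=u,
        p_two_sided=float(p),
        method=method,
        n_a=int(m),
        n_b=int(n),
    )


def compare_conditions(
    summary_a: ConditionSummary,
    summary_b: ConditionSummary,
    *,
    exact_max_total: int = 16,
) -> GroupComparison:
    cmp = mann_whitney_u(
        summary_a.values, summary_b.values, exact_max_total=exact_max_total
    )
    cmp.condition_a = summary_a.condition
    cmp.condition_b = summary_b.condition
    return cmp


def expression_correlation(
    records: Sequence[CellRecord], method: str = "spearman"
) -> ExpressionCorrelation:
    """Correlation between integrated marker expression and per-cell PCC.

    Spearman by default (robust to the skewed expression scale), with
    Pearson selectable. Degenerate (constant) inputs give an undefined-flag
    result; p-values from the t-approximation are flagged approximate below
    n = 10.
    """
    pairs = [
        (r.integrated_marker, r.pcc)
        for r in records
        if not r.is_excluded and math.isfinite(r.integrated_marker)
    ]
    if len(pairs) < 3:
        raise MitolocError("need >= 3 non-excluded records with marker intensities")
    x = np.asarray([p[0] for p in pairs])
    y = np.asarray([p[1] for p in pairs])
    n = x.size
    if np.all(x == x[0]) or np.all(y == y[0]):
        return ExpressionCorrelation(
            rho=float("nan"), p_value=float("nan"), n=n,
            method=method, approximate=n < 10, defined=False,
        )
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise MitolocError(f"unknown correlation method {method!r}")
    return ExpressionCorrelation(
        rho=float(rho), p_value=float(p), n=n, method=method, approximate=n < 10
    )
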