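"""Cohort comparison: Mann-Whitney U test and box-plot summaries.

Recordings are compared metric-by-metric between two groups (e.g. an
earlier and a later period of a surgeon's practice) with the two-sample
Mann-Whitney U test, which makes no distributional assumption and is
appropriate at the small cohort sizes typical of intraoperative studies.

The exact null distribution is computed by counting rank assignments over
the observed midrank multiset, which remains valid under ties; the normal
approximation uses the tie-corrected variance with an optional continuity
correction.  ``U`` is reported as ``min(U_a, U_b)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "MannWhitneyResult",
    "mann_whitney_u",
    "ComparisonRow",
    "compare_groups",
    "BoxStats",
    "summarize_distribution",
]

#: Largest pooled sample size for which the exact method is attempted.
EXACT_LIMIT = 25


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_value: float
    method: str  # "exact" | "normal_approx"


def _rank_sum_distribution(ranks2: np.ndarray, n_a: int) -> dict[int, int]:
    """Counts of doubled-rank sums over all size-``n_a`` subsets.

    Midranks are half-integers, so doubling makes every sum an integer and
    the distribution can be built by dynamic programming over the multiset:
    ``ways[k][s]`` = number of subsets of size ``k`` with doubled sum ``s``.
    """
    ways: list[dict[int, int]] = [dict() for _ in range(n_a + 1)]
    ways[0][0] = 1
    for r in ranks2:
        r = int(r)
        for k in range(min(n_a, len(ranks2)), 0, -1):
            src = ways[k - 1]
            dst = ways[k]
            for s, c in src.items():
                dst[s + r] = dst.get(s + r, 0) + c
    return ways[n_a]


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: str = "auto",
    alternative: str = "two-sided",
    continuity: bool = True,
) -> MannWhitneyResult:
    """Two-sample Mann-Whitney U test.

    ``U = min(U_a, U_b)`` with ``U_a = R_a - n_a(n_a+1)/2`` from pooled
    midranks.  ``method`` is ``"exact"`` (full enumeration of rank
    assignments over the observed midrank multiset — valid under ties),
    ``"normal_approx"`` (tie-corrected variance, continuity correction on
    by default), or ``"auto"`` (exact when ``n_a + n_b <= 25``).  The
    two-sided p is ``P(min(U_A, U_B) <= U_obs)`` under the exact null and
    ``2 * Phi(z)`` (capped at 1) under the approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 1 or n_b < 1:
        raise ValueError("both samples must be non-empty")
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    n = n_a + n_b
    if method not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if n <= EXACT_LIMIT else "normal_approx"
    elif method == "exact" and n > EXACT_LIMIT:
        warnings.warn(
            f"pooled n={n} too large for exact enumeration; "
            "switching to normal approximation",
            RuntimeWarning,
            stacklevel=2,
        )
        method = "normal_approx"

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    u = min(u_a, u_b)

    if method == "exact":
        ranks2 = np.rint(ranks * 2).astype(int)
        dist = _rank_sum_distribution(ranks2, n_a)
        total = sum(dist.values())
        hits = 0
        base2 = n_a * (n_a + 1)  # doubled n_a(n_a+1)/2
        u2_obs = int(round(2 * u))
        for s2, c in dist.items():
            ua2 = s2 - base2
            ub2 = 2 * n_a * n_b - ua2
            if min(ua2, ub2) <= u2_obs:
                hits += c
        p = hits / total
        return MannWhitneyResult(U=u, p_value=p, method="exact")

    # Normal approximation with tie correction.
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MannWhitneyResult(U=u, p_value=1.0, method="normal_approx")
    mean = n_a * n_b / 2.0
    cc = 0.5 if continuity else 0.0
    z = (u - mean + cc) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.cdf(z)))
    p = max(p, np.finfo(float).tiny)
    return MannWhitneyResult(U=u, p_value=p, method="normal_approx")


@dataclass
class ComparisonRow:
    metric: str
    median_a: float | None
    median_b: float | None
    n_a: int
    n_b: int
    U: float | None
    p_value: float | None
    method: str | None

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "median_a": self.median_a,
            "median_b": self.median_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "U": self.U,
            "p_value": self.p_value,
            "method": self.method,
        }


def compare_groups(
    table: pd.DataFrame,
    group_col: str = "group",
    metrics: Sequence[str] | None = None,
    method: str = "auto",
) -> list[ComparisonRow]:
    """Metric-by-metric two-group comparison of a recordings table.

    ``table`` has one row per recording, a group-label column with exactly
    two levels, and one column per metric; NaN marks a metric undefined for
    that recording and is dropped pairwise.  A metric undefined in an
    entire group yields a row with an undefined p.
    """
    groups = list(dict.fromkeys(table[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    ga, gb = groups
    if metrics is None:
        metrics = [c for c in table.columns if c != group_col]
    rows = []
    for metric in metrics:
        va = table.loc[table[group_col] == ga, metric].dropna().to_numpy(float)
        vb = table.loc[table[group_col] == gb, metric].dropna().to_numpy(float)
        med_a = float(np.median(va)) if len(va) else None
        med_b = float(np.median(vb)) if len(vb) else None
        if len(va) and len(vb):
            res = mann_whitney_u(va, vb, method=method)
            rows.append(
                ComparisonRow(metric, med_a, med_b, len(va), len(vb),
                              res.U, res.p_value, res.method)
            )
        else:
            rows.append(
                ComparisonRow(metric, med_a, med_b, len(va), len(vb),
                              None, None, None)
            )
    return rows


@dataclass(frozen=True)
class BoxStats:
    """Five-number box-plot summary with 1.5 IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = field(default_factory=tuple)


def summarize_distribution(values: Sequence[float]) -> BoxStats:
    """Box-plot summary: midpoint-interpolated quartiles, 1.5 IQR whiskers.

    Whiskers sit at the most extreme data points within 1.5 IQR of the
    quartiles; anything beyond is an outlier.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="midpoint")
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(float(x) for x in v[(v < lo_fence) | (v > hi_fence)])
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )
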