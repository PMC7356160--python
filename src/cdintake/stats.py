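"""Classical tests used in the exposure analysis, implemented from first principles.

Statistics and decision rules are hand-coded; only distribution functions
(chi-square, Student t, normal, studentized range) come from scipy.

* :func:`median_test` — Brown–Mood two-sample median test: dichotomise the
  pooled sample at its grand median and test the 2×2 table with Pearson's
  chi-square (ties counted in the ≤ cell; no continuity correction by default).
* :func:`chi_square_2x2` — Pearson chi-square for a 2×2 contingency table.
* :func:`grubbs_iterative` — two-sided Smirnov–Grubbs outlier screening,
  applied iteratively until no point exceeds the critical envelope.
* :func:`steel_dwass` — all-pairs nonparametric multiple comparison via
  pairwise rank sums referred to the studentized-range distribution.
* :func:`t_test_unpaired` — pooled-variance two-sided Student t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class GrubbsOutcome:
    outlier_indices: list[int]  # original indices, in removal order
    g_statistics: list[float]
    critical_values: list[float]
    alpha: float


@dataclass(frozen=True)
class PairwiseResult:
    group_i: int
    group_j: int
    z: float  # standardized rank-sum statistic of group i in the (i, j) pooling
    q: float  # sqrt(2)·|z|, referred to the studentized range
    p_value: float
    significant: bool


def chi_square_2x2(table: Sequence[Sequence[float]], correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2×2 count table (1 df, upper-tail p).

    ``correction`` switches on the Yates continuity correction.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise StatsError("chi_square_2x2 expects a 2x2 table")
    if np.any(obs < 0):
        raise StatsError("counts must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise StatsError("zero marginal in 2x2 table")
    expected = np.outer(row, col) / total
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff**2 / expected))
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(
        statistic=chi2,
        p_value=p,
        method="chi-square 2x2" + (" (Yates)" if correction else ""),
        df=1,
        extra={"expected": expected},
    )


def median_test(
    x: Sequence[float], y: Sequence[float], correction: bool = False
) -> TestResult:
    """Two-sample median test on the pooled grand median.

    Counts per group above vs at-or-below the grand median form a 2×2 table
    tested with Pearson chi-square (1 df). Values equal to the grand median
    fall in the ≤ cell. If all pooled values are identical the table is
    degenerate and p = 1 is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("median_test needs two nonempty samples")
    pooled = np.concatenate([x, y])
    grand = float(np.median(pooled))
    table = np.array(
        [
            [np.count_nonzero(x > grand), np.count_nonzero(x <= grand)],
            [np.count_nonzero(y > grand), np.count_nonzero(y <= grand)],
        ],
        dtype=float,
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # all values on one side of (i.e. equal to) the grand median
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            method="median test (degenerate)",
            df=1,
            extra={"grand_median": grand, "table": table},
        )
    res = chi_square_2x2(table, correction=correction)
    return TestResult(
        statistic=res.statistic,
        p_value=res.p_value,
        method="median test",
        df=1,
        extra={"grand_median": grand, "table": table},
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value: ((n−1)/√n)·√(t²/(n−2+t²)) with t the
    upper α/(2n) Student-t quantile on n−2 df."""
    if n < 3:
        raise StatsError("Grubbs test needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), df=n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_iterative(
    values: Sequence[float], alpha: float = 0.05, max_removals: int | None = None
) -> GrubbsOutcome:
    """Iteratively remove the most extreme point while its Grubbs statistic
    G = max|xᵢ − mean| / sd exceeds the critical value.

    Returns the removed points' original indices in removal order together
    with the per-iteration G and critical values. Zero-variance data yield no
    removals.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise StatsError("Grubbs test needs n >= 3")
    active = np.arange(arr.size)
    outcome = GrubbsOutcome([], [], [], alpha)
    while active.size >= 3:
        if max_removals is not None and len(outcome.outlier_indices) >= max_removals:
            break
        sub = arr[active]
        mean = sub.mean()
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - mean)
        k = int(np.argmax(dev))
        g = float(dev[k] / sd)
        crit = grubbs_critical_value(active.size, alpha)
        if g <= crit:
            break
        outcome.outlier_indices.append(int(active[k]))
        outcome.g_statistics.append(g)
        outcome.critical_values.append(crit)
        active = np.delete(active, k)
    return outcome


def _tie_factor(pooled: np.ndarray) -> float:
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    ties = counts[counts > 1]
    if ties.size == 0 or n < 2:
        return 1.0
    return 1.0 - float(np.sum(ties**3 - ties)) / (n**3 - n)


def steel_dwass(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> list[PairwiseResult]:
    """Steel–Dwass all-pairs comparison (large-sample studentized-range form).

    For each pair the two groups are pooled alone and mid-ranked; the rank sum
    of the first group is standardized with mean nᵢ(nᵢ+nⱼ+1)/2 and
    tie-corrected variance nᵢnⱼ(nᵢ+nⱼ+1)/12 × tie factor. √2·|z| is referred
    to the studentized-range distribution for k groups and ∞ df, which
    controls the family-wise error at ``alpha``. Pairs involving a group with
    fewer than 2 observations are skipped.
    """
    k = len(groups)
    if k < 2:
        raise StatsError("steel_dwass needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, np.inf))
    results: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = arrays[i], arrays[j]
            if gi.size < 2 or gj.size < 2:
                continue
            pooled = np.concatenate([gi, gj])
            ranks = sps.rankdata(pooled)
            n_i, n_j = gi.size, gj.size
            big_n = n_i + n_j
            r_i = float(ranks[:n_i].sum())
            mean = n_i * (big_n + 1) / 2.0
            var = n_i * n_j * (big_n + 1) / 12.0 * _tie_factor(pooled)
            if var == 0.0:
                z = 0.0
            else:
                z = (r_i - mean) / math.sqrt(var)
            q = math.sqrt(2.0) * abs(z)
            p = float(sps.studentized_range.sf(q, k, np.inf))
            results.append(
                PairwiseResult(
                    group_i=i,
                    group_j=j,
                    z=float(z),
                    q=q,
                    p_value=min(max(p, 0.0), 1.0),
                    significant=q > q_crit,
                )
            )
    return results


def t_test_unpaired(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided pooled-variance (Student) t-test for independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError("t_test_unpaired needs n >= 2 in each sample")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if pooled_var == 0.0:
        t = 0.0 if x.mean() == y.mean() else math.inf
        p = 1.0 if t == 0.0 else 0.0
        return TestResult(statistic=t, p_value=p, method="unpaired t-test", df=df)
    se = math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = float((x.mean() - y.mean()) / se)
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return TestResult(statistic=t, p_value=p, method="unpaired t-test", df=df)
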