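"""Contamination index and group comparison statistics.

The index for a sample is r = (contaminant-specific read count) /
(host-specific read count); groups are compared by fold change of group
means and by an exact two-tailed Mann-Whitney U test (with a
continuity-corrected normal approximation for large samples), or by the
unpaired pooled-variance t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import ClassificationResult

__all__ = [
    "ContaminationIndex",
    "FoldChangeResult",
    "MannWhitneyResult",
    "TTestResult",
    "UndefinedIndexError",
    "contamination_index",
    "fold_change",
    "mann_whitney_exact",
    "t_test_unpaired",
    "estimate_mixture_fraction",
    "table_report",
    "EXACT_ENUMERATION_LIMIT",
]

#: Exact Mann-Whitney enumeration is used while C(n+m, n) stays below this.
EXACT_ENUMERATION_LIMIT = 100_000


class UndefinedIndexError(ZeroDivisionError):
    """The contamination index is undefined (no host-specific reads)."""


@dataclass(frozen=True)
class ContaminationIndex:
    """Per-sample contamination index r = n_specific_b / n_specific_a."""

    sample_id: str | None
    n_specific_b: int
    n_specific_a: int

    @property
    def r(self) -> float:
        return self.n_specific_b / self.n_specific_a


def contamination_index(
    result: ClassificationResult | None = None,
    *,
    n_specific_a: int | None = None,
    n_specific_b: int | None = None,
    sample_id: str | None = None,
) -> ContaminationIndex:
    """Contamination index from a classification result (or raw counts).

    Raises :class:`UndefinedIndexError` when the host-specific count is
    zero; callers exclude such samples downstream with a warning.
    """
    if result is not None:
        n_specific_a = result.n_specific_a
        n_specific_b = result.n_specific_b
        sample_id = sample_id or result.sample_id
    assert n_specific_a is not None and n_specific_b is not None
    if n_specific_a == 0:
        raise UndefinedIndexError(
            f"sample {sample_id!r}: no host-specific (A) reads; "
            "contamination index undefined"
        )
    return ContaminationIndex(sample_id=sample_id, n_specific_b=n_specific_b,
                              n_specific_a=n_specific_a)


def _mean_sem(values: Sequence[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    # SEM is undefined for a single observation and reported blank.
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else None
    return mean, sem


@dataclass(frozen=True)
class FoldChangeResult:
    """Fold change of group means, with per-group mean +/- SEM."""

    fc: float
    mean_numerator: float
    sem_numerator: float | None
    mean_denominator: float
    sem_denominator: float | None
    n_numerator: int
    n_denominator: int


def fold_change(
    group_numerator: Sequence[float], group_denominator: Sequence[float]
) -> FoldChangeResult:
    """FC = mean(numerator group) / mean(denominator group).

    This is a ratio of group means, not a mean of per-sample ratios.
    """
    if len(group_numerator) == 0 or len(group_denominator) == 0:
        raise ValueError("both groups must be non-empty")
    mean_n, sem_n = _mean_sem(group_numerator)
    mean_d, sem_d = _mean_sem(group_denominator)
    if mean_d == 0:
        raise ZeroDivisionError("denominator group mean is zero; FC undefined")
    return FoldChangeResult(
        fc=mean_n / mean_d,
        mean_numerator=mean_n,
        sem_numerator=sem_n,
        mean_denominator=mean_d,
        sem_denominator=sem_d,
        n_numerator=len(group_numerator),
        n_denominator=len(group_denominator),
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #{x_i < y_j} + 0.5 * #{x_i == y_j}."""
    less = (x[:, None] < y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(less) + 0.5 * float(ties)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_two_tailed: float
    method: str  # "exact" or "normal_approx"
    n_x: int
    n_y: int


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    enumeration_limit: int = EXACT_ENUMERATION_LIMIT,
) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test, exact by full enumeration.

    U = min(U_x, U_y) with ties credited 1/2. The exact two-tailed p is
    twice the smaller tail of the permutation distribution of U_x, capped
    at 1, enumerating all C(n+m, n) group assignments of the pooled
    (possibly tied) values. When the enumeration exceeds
    ``enumeration_limit`` assignments, a normal approximation with
    continuity and tie correction is used and flagged in ``method``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = xa.size, ya.size
    u_x = _u_statistic(xa, ya)
    u_y = _u_statistic(ya, xa)
    u_min = min(u_x, u_y)

    if math.comb(n + m, n) <= enumeration_limit:
        pool = np.concatenate([xa, ya])
        # Pairwise "wins" over pooled values; U for an assignment is the sum
        # of wins of the x-subset against its complement. Doubled wins keep
        # the enumeration in exact integer arithmetic despite 1/2 ties.
        wins2 = (
            2 * (pool[:, None] < pool[None, :]) + (pool[:, None] == pool[None, :])
        ).astype(np.int64)
        np.fill_diagonal(wins2, 0)
        w2 = wins2.tolist()
        row_tot = [sum(r) for r in w2]
        u2_obs = round(2 * u_x)
        nm = n + m
        count_low = 0
        count_high = 0
        total = 0
        for subset in combinations(range(nm), n):
            # wins of subset vs complement = wins vs everyone - wins within.
            u2 = sum(row_tot[i] for i in subset)
            for i in subset:
                wi = w2[i]
                for j in subset:
                    u2 -= wi[j]
            total += 1
            if u2 <= u2_obs:
                count_low += 1
            if u2 >= u2_obs:
                count_high += 1
        # Two-tailed: double the smaller tail of the permutation
        # distribution of U_x (equivalently, of U_y), capped at 1.
        p = min(1.0, 2.0 * min(count_low, count_high) / total)
        return MannWhitneyResult(u=u_min, p_two_tailed=p, method="exact",
                                 n_x=n, n_y=m)

    # Normal approximation with tie correction and continuity correction.
    pool = np.concatenate([xa, ya])
    _, tie_counts = np.unique(pool, return_counts=True)
    nm = n + m
    mu = n * m / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (nm * (nm - 1))
    sigma2 = n * m / 12.0 * (nm + 1 - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u=u_min, p_two_tailed=1.0,
                                 method="normal_approx", n_x=n, n_y=m)
    z = (u_min - mu + 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(sps.norm.cdf(z)))
    return MannWhitneyResult(u=u_min, p_two_tailed=p, method="normal_approx",
                             n_x=n, n_y=m)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_two_tailed: float
    df: int


def t_test_unpaired(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Unpaired two-tailed pooled-variance t-test.

    By convention, two groups with zero variance and equal means give
    t = 0, p = 1 rather than an indeterminate statistic.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each group needs at least 2 observations")
    n, m = xa.size, ya.size
    df = n + m - 2
    sp2 = ((n - 1) * xa.var(ddof=1) + (m - 1) * ya.var(ddof=1)) / df
    delta = xa.mean() - ya.mean()
    if sp2 == 0:
        if delta == 0:
            return TTestResult(t=0.0, p_two_tailed=1.0, df=df)
        t = math.inf if delta > 0 else -math.inf
        return TTestResult(t=t, p_two_tailed=0.0, df=df)
    t = delta / math.sqrt(sp2 * (1.0 / n + 1.0 / m))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), p_two_tailed=min(1.0, p), df=df)


def estimate_mixture_fraction(r: float | ContaminationIndex) -> float:
    """Contamination fraction estimate c_hat = r / (1 + r).

    Exact inversion of the index under the idealization that cross-species
    mapping affects both species symmetrically (an approximation on real
    genomes when cross-mapping is negligible or balanced).
    """
    rv = r.r if isinstance(r, ContaminationIndex) else float(r)
    if rv < 0:
        raise ValueError("index must be non-negative")
    return rv / (1.0 + rv)


def _fmt_mean_sem(mean: float, sem: float | None, digits: int = 3) -> str:
    if sem is None:
        return f"{mean:.{digits}g}"
    return f"{mean:.{digits}g} ± {sem:.{digits}g}"


def table_report(
    indices: pd.DataFrame,
    numerator_group: str = "exosomal",
    denominator_group: str = "cellular",
) -> tuple[pd.DataFrame, MannWhitneyResult]:
    """Per-dataset group summary plus one global Mann-Whitney test.

    ``indices`` needs columns sample_id, dataset, group, index. Datasets
    where either group is empty, or whose denominator mean is zero, are
    reported with FC = NaN. The significance test pools all samples across
    datasets (a single global comparison; per-dataset tests are not run).
    """
    required = {"sample_id", "dataset", "group", "index"}
    missing = required - set(indices.columns)
    if missing:
        raise ValueError(f"indices table missing columns: {sorted(missing)}")
    rows = []
    for dataset, sub in indices.groupby("dataset", sort=True):
        num = sub.loc[sub["group"] == numerator_group, "index"].tolist()
        den = sub.loc[sub["group"] == denominator_group, "index"].tolist()
        row: dict = {"dataset": dataset}
        if den:
            mean_d, sem_d = _mean_sem(den)
            row[denominator_group] = _fmt_mean_sem(mean_d, sem_d)
        if num:
            mean_n, sem_n = _mean_sem(num)
            row[numerator_group] = _fmt_mean_sem(mean_n, sem_n)
        if num and den:
            try:
                row["fc"] = fold_change(num, den).fc
            except ZeroDivisionError:
                row["fc"] = float("nan")
            row["n"] = f"{len(den)} vs {len(num)}"
        rows.append(row)
    table = pd.DataFrame(rows)
    x = indices.loc[indices["group"] == numerator_group, "index"].tolist()
    y = indices.loc[indices["group"] == denominator_group, "index"].tolist()
    test = mann_whitney_exact(x, y)
    return table, test
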