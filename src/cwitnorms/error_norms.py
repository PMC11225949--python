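"""Normative treatment of CWIT-3/4 error counts.

Error counts on the inhibition subtests are zero-inflated and
over-dispersed, and their association with demographics is too weak to
justify adjustment, so error norms are plain cumulative percentages of
the unstratified sample: the proportion attaining k errors or more.

The module also provides the demographic association screen (Spearman
rho for age/education, Mann-Whitney with rank-biserial correlation for
sex, Pearson r with completion time) and the extreme-group comparison of
completion times between participants with zero errors and those with
four or more on either subtest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort_io import CohortTable, ERROR_SUBTESTS, Subtest

__all__ = [
    "ErrorNormTable",
    "cumulative_error_table",
    "AssociationScreen",
    "screen_associations",
    "WelchResult",
    "compare_extreme_groups",
    "LOW_AVERAGE_ERROR_THRESHOLD",
]

#: >= this many errors on either subtest marks a "low average" performance.
LOW_AVERAGE_ERROR_THRESHOLD = 4


@dataclass(frozen=True)
class ErrorNormTable:
    """Cumulative error percentages: cumulative[k] = % with >= k errors."""

    subtest: Subtest
    cumulative: Mapping[int, float]
    n_available: int

    def __post_init__(self) -> None:
        if self.cumulative.get(0) != 100.0:
            raise ValueError("cumulative(0) must be 100")
        ks = sorted(self.cumulative)
        vals = [self.cumulative[k] for k in ks]
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("cumulative percentages must be non-increasing in k")
        if any(not (0.0 <= v <= 100.0) for v in vals):
            raise ValueError("cumulative percentages must lie in [0, 100]")

    def percentile_of(self, k: int) -> float:
        """Percentage of the normative sample with >= k errors (observed k)."""
        if k in self.cumulative:
            return self.cumulative[k]
        observed = [kk for kk in self.cumulative if kk <= k]
        # unobserved count: the cumulative proportion of the next observed
        # count above applies (no participant sits at k exactly)
        above = [kk for kk in self.cumulative if kk > k]
        return self.cumulative[min(above)] if above else 0.0


def cumulative_error_table(
    errors: Sequence[float | None], subtest: Subtest
) -> ErrorNormTable:
    """Cumulative error percentages from a collection of counts.

    Missing entries (None/NaN) are excluded; cumulative(k) is reported
    for every observed k (blanks at unobserved counts mean nobody made
    exactly that many errors, not a zero cumulative).
    """
    clean = [
        int(e)
        for e in errors
        if e is not None and not (isinstance(e, float) and math.isnan(e))
    ]
    if not clean:
        raise ValueError(f"{subtest}: no non-missing error counts")
    arr = np.asarray(clean)
    n = arr.size
    ks = sorted(set(arr.tolist()) | {0})
    cumulative = {k: 100.0 * float(np.sum(arr >= k)) / n for k in ks}
    return ErrorNormTable(subtest=subtest, cumulative=cumulative, n_available=n)


@dataclass(frozen=True)
class AssociationScreen:
    """Screen of one subtest's error counts against demographics and time.

    Entries are None where the correlation is undefined (constant input).
    """

    subtest: Subtest
    spearman_age: float | None
    spearman_age_p: float | None
    spearman_edu: float | None
    spearman_edu_p: float | None
    rank_biserial_sex: float | None
    mannwhitney_u: float | None
    mannwhitney_p: float | None
    pearson_time: float | None
    pearson_time_p: float | None
    pearson_time_ci95: tuple[float, float] | None
    n: int = 0


def _fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + conf / 2.0)
    return (math.tanh(z - q * se), math.tanh(z + q * se))


def _mann_whitney_asymptotic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation,
    no continuity correction.  Returns (U of the first sample, p)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def screen_associations(
    cohort: CohortTable, subtest: Subtest = Subtest.CWIT3
) -> AssociationScreen:
    """Assess whether error norms need demographic adjustment.

    Complete cases only (errors and the same subtest's completion time
    present).  Requires at least 10 such cases.
    """
    if subtest not in ERROR_SUBTESTS:
        raise ValueError(f"errors are only recorded on CWIT-3/4, got {subtest}")
    rows = [
        (r.errors[subtest], r.age, r.education, r.female, r.times.get(subtest))
        for r in cohort
        if subtest in r.errors and subtest in r.times
    ]
    if len(rows) < 10:
        raise ValueError(f"need at least 10 complete cases, got {len(rows)}")
    err, age, edu, fem, time = (np.asarray(col, dtype=float) for col in zip(*rows))
    n = err.size

    def spearman(x: np.ndarray) -> tuple[float | None, float | None]:
        if np.ptp(x) == 0 or np.ptp(err) == 0:
            return None, None
        rho, p = stats.spearmanr(err, x)
        return float(rho), float(p)

    rho_age, p_age = spearman(age)
    rho_edu, p_edu = spearman(edu)

    if np.ptp(fem) == 0 or np.ptp(err) == 0:
        rb = u = p_mw = None
    else:
        male_err, female_err = err[fem == 0], err[fem == 1]
        u, p_mw = _mann_whitney_asymptotic(male_err, female_err)
        rb = 1.0 - 2.0 * u / (male_err.size * female_err.size)

    if np.ptp(time) == 0 or np.ptp(err) == 0:
        r_time = p_time = ci = None
    else:
        r_time, p_time = (float(v) for v in stats.pearsonr(err, time))
        ci = _fisher_ci(r_time, n)

    return AssociationScreen(
        subtest=subtest,
        spearman_age=rho_age,
        spearman_age_p=p_age,
        spearman_edu=rho_edu,
        spearman_edu_p=p_edu,
        rank_biserial_sex=rb,
        mannwhitney_u=u,
        mannwhitney_p=p_mw,
        pearson_time=r_time,
        pearson_time_p=p_time,
        pearson_time_ci95=ci,
        n=n,
    )


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t-test of completion times between error groups."""

    subtest: Subtest
    mean_zero: float
    sd_zero: float
    n_zero: int
    mean_high: float
    sd_high: float
    n_high: int
    mean_diff: float  # zero-error group minus high-error group
    t: float
    df: float
    p: float


def compare_extreme_groups(
    cohort: CohortTable, threshold: int = LOW_AVERAGE_ERROR_THRESHOLD
) -> dict[Subtest, WelchResult]:
    """Compare completion times between zero-error and high-error groups.

    Group membership is defined across subtests: the high group made
    >= ``threshold`` errors on either CWIT-3 or CWIT-4, the zero group
    made none on either.  Each subtest's completion times are then
    compared with Welch's t-test (no equal-variance assumption,
    Satterthwaite degrees of freedom).
    """
    zero_ids, high_ids = set(), set()
    for r in cohort:
        observed = [r.errors[st] for st in ERROR_SUBTESTS if st in r.errors]
        if not observed:
            continue
        if any(e >= threshold for e in observed):
            high_ids.add(r.id)
        elif len(observed) == len(ERROR_SUBTESTS) and all(e == 0 for e in observed):
            zero_ids.add(r.id)
    results: dict[Subtest, WelchResult] = {}
    for st in ERROR_SUBTESTS:
        t_zero = np.asarray(
            [r.times[st] for r in cohort if r.id in zero_ids and st in r.times], float
        )
        t_high = np.asarray(
            [r.times[st] for r in cohort if r.id in high_ids and st in r.times], float
        )
        if t_zero.size == 0 or t_high.size == 0:
            raise ValueError(
                f"{st}: threshold {threshold} leaves an empty comparison group "
                f"(zero n={t_zero.size}, high n={t_high.size})"
            )
        res = stats.ttest_ind(t_zero, t_high, equal_var=False)
        v0, v1 = t_zero.var(ddof=1), t_high.var(ddof=1)
        n0, n1 = t_zero.size, t_high.size
        df = (v0 / n0 + v1 / n1) ** 2 / (
            (v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1)
        )
        results[st] = WelchResult(
            subtest=st,
            mean_zero=float(t_zero.mean()),
            sd_zero=float(t_zero.std(ddof=1)),
            n_zero=n0,
            mean_high=float(t_high.mean()),
            sd_high=float(t_high.std(ddof=1)),
            n_high=n1,
            mean_diff=float(t_zero.mean() - t_high.mean()),
            t=float(res.statistic),
            df=float(df),
            p=float(res.pvalue),
        )
    return results
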