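"""Test-retest stability: interval filtering, ICC(A,1), and RCIs.

Stability of normed scores across two occasions is quantified with the
intraclass correlation for a single rating under an absolute-agreement
two-way mixed-effects model, ICC(A,1):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the between-subject, between-occasion, and error mean
squares of the two-way ANOVA and k = 2 occasions.  The 95% CI follows
the F-distribution construction of McGraw & Wong.  Absolute agreement
(rather than consistency) means a systematic shift between occasions —
e.g. a practice effect — lowers the coefficient.

The Reliable Change Index standardizes an individual's change score by
the standard error of the measurement difference; the three canonical
variants (Jacobson-Traux, practice-adjusted, regression-based) are
provided, along with the materials table (means, SDs, r12) needed to
compute them from published statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortTable, Subtest
from .norm_scoring import NormSet, score_batch

__all__ = [
    "RetestPair",
    "filter_retest",
    "ICCResult",
    "icc_a1",
    "RCIMaterials",
    "RCIResult",
    "rci",
    "StabilityReport",
    "stability_report",
    "stability_band",
]


@dataclass(frozen=True)
class RetestPair:
    """Baseline/follow-up scores for one person with the retest interval."""

    id: str
    baseline: float
    followup: float
    interval_years: float

    def __post_init__(self) -> None:
        if self.interval_years <= 0:
            raise ValueError("interval must be positive")


def filter_retest(
    pairs: Iterable[RetestPair], max_interval: float = 5.0
) -> tuple[list[RetestPair], int]:
    """Retain pairs retested within ``max_interval`` years; count exclusions."""
    pairs = list(pairs)
    retained = [p for p in pairs if p.interval_years <= max_interval]
    return retained, len(pairs) - len(retained)


def stability_band(icc: float) -> str:
    """Conventional reliability classification of an ICC point estimate."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ICCResult:
    """ICC(A,1) with its two-way ANOVA mean squares and 95% CI."""

    icc: float
    ci95: tuple[float, float]
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int = 2

    def __post_init__(self) -> None:
        if not (-1.0 < self.icc <= 1.0 + 1e-12):
            raise ValueError(f"ICC {self.icc} outside (-1, 1]")

    @property
    def band(self) -> str:
        return stability_band(self.icc)


def icc_a1(pairs: Sequence[RetestPair], conf: float = 0.95) -> ICCResult:
    """Single-rating absolute-agreement two-way ICC from retest pairs.

    The two occasions are the "raters" of the two-way layout.  Requires
    at least 5 complete pairs and non-zero between-subject variance.
    """
    data = np.asarray([(p.baseline, p.followup) for p in pairs], dtype=float)
    if data.shape[0] < 5:
        raise ValueError(f"need at least 5 complete pairs, got {data.shape[0]}")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_error = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    if msr <= 0:
        raise ValueError("zero variance across subjects; ICC undefined")
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based CI for ICC(A,1)
    alpha = 1.0 - conf
    if mse <= 0:  # perfect agreement
        return ICCResult(icc=1.0, ci95=(1.0, 1.0), ms_rows=msr, ms_cols=msc,
                         ms_error=mse, n=n, k=k)
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    lower, upper = min(lower, icc), max(upper, icc)
    return ICCResult(
        icc=float(icc), ci95=(float(lower), float(upper)),
        ms_rows=msr, ms_cols=msc, ms_error=mse, n=n, k=k,
    )


# ------------------------------------------------------------------ RCI


@dataclass(frozen=True)
class RCIMaterials:
    """Statistics needed to compute RCIs from published tables."""

    sd_baseline: float
    r12: float
    mean_practice: float = 0.0  # mean follow-up minus baseline
    slope: float | None = None  # regression-based: follow ~ slope*base + intercept
    intercept: float | None = None
    see: float | None = None  # standard error of estimate of that regression

    def __post_init__(self) -> None:
        if not (0.0 < self.r12 < 1.0):
            raise ValueError(f"r12 must be in (0, 1), got {self.r12}")
        if self.sd_baseline <= 0:
            raise ValueError("sd_baseline must be positive")

    @property
    def sem(self) -> float:
        """Standard error of measurement: SD_baseline * sqrt(1 - r12)."""
        return self.sd_baseline * math.sqrt(1.0 - self.r12)

    @property
    def se_diff(self) -> float:
        """Standard error of the measurement difference: sqrt(2) * SEM."""
        return math.sqrt(2.0) * self.sem


@dataclass(frozen=True)
class RCIResult:
    method: str
    statistic: float
    critical: float = 1.96

    @property
    def significant(self) -> bool:
        return abs(self.statistic) > self.critical


def rci(
    baseline: float,
    followup: float,
    materials: RCIMaterials,
    method: str = "jacobson_truax",
) -> RCIResult:
    """Reliable Change Index of one person's baseline -> follow-up change.

    jacobson_truax:     (follow - base) / SEdiff
    practice_adjusted:  (follow - base - mean_practice) / SEdiff
    regression_based:   (follow - (slope*base + intercept)) / SEE
    """
    if method in ("jacobson_truax", "practice_adjusted"):
        change = followup - baseline
        if method == "practice_adjusted":
            change -= materials.mean_practice
        statistic = change / materials.se_diff
    elif method == "regression_based":
        if materials.slope is None or materials.intercept is None or materials.see is None:
            raise ValueError("regression_based RCI needs slope, intercept and SEE")
        if materials.see <= 0:
            raise ValueError("SEE must be positive")
        predicted = materials.slope * baseline + materials.intercept
        statistic = (followup - predicted) / materials.see
    else:
        raise ValueError(f"unknown RCI method {method!r}")
    return RCIResult(method=method, statistic=float(statistic))


# ------------------------------------------------------- full pipeline


@dataclass
class StabilityReport:
    """Per-subtest ICCs on normed T-scores plus RCI materials."""

    icc: dict[Subtest, ICCResult]
    materials: dict[Subtest, RCIMaterials]
    summary_stats: pd.DataFrame  # per subtest: means/SDs both occasions, r12, n
    n_excluded: int
    max_interval: float


def _retest_pairs_from_scores(
    base: pd.DataFrame, follow: pd.DataFrame, intervals: Mapping[str, float],
    subtest: Subtest, value: str,
) -> list[RetestPair]:
    b = base[base["subtest"] == subtest.value].set_index("id")[value]
    f = follow[follow["subtest"] == subtest.value].set_index("id")[value]
    common = b.index.intersection(f.index)
    return [
        RetestPair(
            id=str(i), baseline=float(b[i]), followup=float(f[i]),
            interval_years=float(intervals[i]),
        )
        for i in common
        if i in intervals
    ]


def stability_report(
    cohort: CohortTable,
    normset: NormSet,
    max_interval: float = 5.0,
    *,
    use_raw: bool = False,
) -> StabilityReport:
    """ICCs and RCI materials for a longitudinal cohort scored with a norm set.

    Baseline and follow-up times are scored with the same norms, pairs
    retested more than ``max_interval`` years apart are excluded, and
    ICC(A,1) is computed per subtest on T-scores (or raw times with
    ``use_raw=True``).
    """
    intervals = {
        r.id: r.interval_years for r in cohort if r.interval_years is not None
    }
    if not intervals:
        raise ValueError("cohort has no retest intervals; longitudinal schema required")
    if any(not r.times_followup for r in cohort if r.id in intervals):
        pass  # participants without follow-up scores simply contribute no pairs
    base_scores = score_batch(normset, cohort)
    follow_scores = score_batch(normset, cohort, followup=True)
    value = "raw" if use_raw else "t"
    icc_out: dict[Subtest, ICCResult] = {}
    materials: dict[Subtest, RCIMaterials] = {}
    rows = []
    n_excluded_total = 0
    for st in normset.subtests:
        pairs = _retest_pairs_from_scores(base_scores, follow_scores, intervals, st, value)
        retained, n_excl = filter_retest(pairs, max_interval)
        n_excluded_total = max(n_excluded_total, n_excl)
        if len(retained) < 5:
            continue
        icc_out[st] = icc_a1(retained)
        b = np.asarray([p.baseline for p in retained])
        f = np.asarray([p.followup for p in retained])
        r12 = float(np.corrcoef(b, f)[0, 1])
        r12 = min(max(r12, 1e-6), 1 - 1e-6)
        slope, intercept = np.polyfit(b, f, 1)
        see = float(np.sqrt(np.sum((f - (slope * b + intercept)) ** 2) / (b.size - 2)))
        materials[st] = RCIMaterials(
            sd_baseline=float(b.std(ddof=1)),
            r12=r12,
            mean_practice=float((f - b).mean()),
            slope=float(slope),
            intercept=float(intercept),
            see=see,
        )
        rows.append(
            {
                "subtest": st.value,
                "n": b.size,
                "mean_baseline": b.mean(),
                "sd_baseline": b.std(ddof=1),
                "mean_followup": f.mean(),
                "sd_followup": f.std(ddof=1),
                "r12": r12,
                "icc": icc_out[st].icc,
                "icc_ci_low": icc_out[st].ci95[0],
                "icc_ci_high": icc_out[st].ci95[1],
                "band": icc_out[st].band,
            }
        )
    return StabilityReport(
        icc=icc_out,
        materials=materials,
        summary_stats=pd.DataFrame(rows),
        n_excluded=n_excluded_total,
        max_interval=max_interval,
    )
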