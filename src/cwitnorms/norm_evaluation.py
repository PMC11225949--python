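"""Auditing a norm set against a cohort.

Well-adjusted norms leave no demographic signal in the standardized
scores: regressing T-scores on age, education, and sex should find
nothing.  A significant coefficient flags a maladjustment (the norms
under- or over-correct for that variable).  Two norm sets applied to the
same people are compared with paired t-tests on the T-scores, and the
rate of low scores (T below 35, i.e. 1.5 SD below the normative mean) is
tested against the theoretical base rate of a normal distribution with
one-proportion Z-tests, Wilson 99% confidence intervals, and — between
two norm sets — the asymptotic McNemar test without continuity
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .normative_regression import fit_ols

__all__ = [
    "theoretical_low_score_rate",
    "MaladjustmentResult",
    "maladjustment_regression",
    "PairedComparison",
    "paired_norm_comparison",
    "BaseRateResult",
    "base_rate_analysis",
    "McNemarResult",
    "mcnemar_paired",
    "wilson_ci",
]

#: T-score cutoff defining a low score (1.5 SD below the normative mean).
DEFAULT_CUTOFF_T = 35.0


def theoretical_low_score_rate(sd_below: float = 1.5) -> float:
    """Expected % of a normal population below ``sd_below`` SDs (6.7 for 1.5)."""
    return 100.0 * float(stats.norm.cdf(-sd_below))


# ------------------------------------------------- maladjustment audit


@dataclass(frozen=True)
class MaladjustmentResult:
    """One subtest's regression of T-scores on demographics.

    ``coefficients`` maps predictor -> {b, se, t, p, partial_r2, flagged};
    a flagged predictor indicates the norms failed to remove its effect.
    """

    coefficients: Mapping[str, Mapping[str, float | bool]]
    adj_r2: float
    n: int
    alpha: float

    @property
    def flagged(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.coefficients.items() if v["flagged"])


def maladjustment_regression(
    tscores: Sequence[float],
    ages: Sequence[float],
    educations: Sequence[float],
    females: Sequence[int],
    alpha_eval: float = 0.05,
) -> MaladjustmentResult:
    """Regress T-scores on mean-centered age/education and sex.

    A predictor with p < alpha_eval is flagged as a maladjustment.
    Requires at least 50 complete cases.
    """
    t = np.asarray(tscores, dtype=float)
    mask = ~np.isnan(t)
    t = t[mask]
    age = np.asarray(ages, dtype=float)[mask]
    edu = np.asarray(educations, dtype=float)[mask]
    fem = np.asarray(females, dtype=float)[mask]
    if t.size < 50:
        raise ValueError(f"need at least 50 complete cases, got {t.size}")
    X = np.column_stack([np.ones_like(t), age - age.mean(), edu - edu.mean(), fem])
    fitted = fit_ols(X, t, ("age", "education", "female"))
    coeffs = {}
    for i, name in enumerate(("intercept", "age", "education", "female")):
        coeffs[name] = {
            "b": float(fitted.params[i]),
            "se": float(fitted.bse[i]),
            "t": float(fitted.tvalues[i]),
            "p": float(fitted.pvalues[i]),
            "partial_r2": float(fitted.partial_r2[i]) if i > 0 else float("nan"),
            "flagged": bool(i > 0 and fitted.pvalues[i] < alpha_eval),
        }
    return MaladjustmentResult(
        coefficients=coeffs, adj_r2=fitted.adj_r2, n=int(t.size), alpha=alpha_eval
    )


# --------------------------------------------------- paired comparison


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test of T-scores from two norm sets on the same people."""

    mean_a: float
    mean_b: float
    mean_diff: float  # A - B
    sd_diff: float
    ci95: tuple[float, float]
    t: float
    df: int
    p: float
    cohens_d: float  # mean difference / SD of differences
    n: int


def paired_norm_comparison(
    tscores_a: Sequence[float], tscores_b: Sequence[float]
) -> PairedComparison:
    a = np.asarray(tscores_a, dtype=float)
    b = np.asarray(tscores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"pairing error: lengths {a.shape} vs {b.shape}")
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if a.size < 2:
        raise ValueError("need at least 2 complete pairs")
    d = a - b
    n = d.size
    sd = float(d.std(ddof=1))
    se = sd / math.sqrt(n)
    t = float(d.mean() / se) if se > 0 else 0.0
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df)) if se > 0 else 1.0
    q = float(stats.t.ppf(0.975, df))
    return PairedComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_diff=float(d.mean()),
        sd_diff=sd,
        ci95=(float(d.mean() - q * se), float(d.mean() + q * se)),
        t=t,
        df=df,
        p=p,
        cohens_d=float(d.mean() / sd) if sd > 0 else 0.0,
        n=n,
    )


# ------------------------------------------------------ base-rate audit


def wilson_ci(count: int, n: int, conf: float = 0.99) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(count, n, alpha=1.0 - conf, method="wilson")
    return float(lo), float(hi)


@dataclass(frozen=True)
class BaseRateResult:
    """Observed low-score rate versus the theoretical base rate."""

    n: int
    count_below: int
    proportion_pct: float
    expected_pct: float
    ci99_pct: tuple[float, float]
    z: float
    p: float

    def __post_init__(self) -> None:
        if not (self.ci99_pct[0] - 1e-9 <= self.proportion_pct <= self.ci99_pct[1] + 1e-9):
            raise ValueError("confidence interval must contain the sample proportion")

    @property
    def significant_at_01(self) -> bool:
        return self.p < 0.01


def base_rate_analysis(
    tscores: Sequence[float],
    cutoff_t: float = DEFAULT_CUTOFF_T,
    expected_pct: float | None = None,
) -> BaseRateResult:
    """One-proportion Z-test of the low-score rate (strict T < cutoff).

    The expected rate defaults to the theoretical normal base rate below
    1.5 SD (6.7%).  No continuity correction; the 99% CI is a Wilson
    score interval.
    """
    t = np.asarray(tscores, dtype=float)
    t = t[~np.isnan(t)]
    n = t.size
    if n < 30:
        raise ValueError(f"need at least 30 scores, got {n}")
    if expected_pct is None:
        expected_pct = theoretical_low_score_rate()
    count = int(np.sum(t < cutoff_t))
    p_hat = count / n
    p0 = expected_pct / 100.0
    se = math.sqrt(p0 * (1.0 - p0) / n)
    z = (p_hat - p0) / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    lo, hi = wilson_ci(count, n, conf=0.99)
    return BaseRateResult(
        n=n,
        count_below=count,
        proportion_pct=100.0 * p_hat,
        expected_pct=expected_pct,
        ci99_pct=(100.0 * lo, 100.0 * hi),
        z=z,
        p=p,
    )


# ------------------------------------------------------------- McNemar


@dataclass(frozen=True)
class McNemarResult:
    """Asymptotic McNemar test on discordant low-score flags."""

    b: int  # flagged by A only
    c: int  # flagged by B only
    chi2: float
    p: float
    degenerate: bool = False  # no discordant pairs; p reported as 1

    def __post_init__(self) -> None:
        if self.b + self.c > 0:
            expected = (self.b - self.c) ** 2 / (self.b + self.c)
            if abs(self.chi2 - expected) > 1e-9:
                raise ValueError("chi2 must equal (b-c)^2/(b+c)")


def mcnemar_paired(
    flags_a: Sequence[bool], flags_b: Sequence[bool]
) -> McNemarResult:
    """Paired proportion test, asymptotic, no continuity correction.

    chi2 = (b - c)^2 / (b + c) on the discordant counts with 1 df.  When
    there are no discordant pairs the statistic is undefined and p = 1 is
    reported with the degenerate note.
    """
    a = np.asarray(flags_a, dtype=bool)
    bb = np.asarray(flags_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError(f"pairing error: lengths {a.shape} vs {bb.shape}")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    if b + c == 0:
        return McNemarResult(b=0, c=0, chi2=0.0, p=1.0, degenerate=True)
    chi2 = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, 1))
    return McNemarResult(b=b, c=c, chi2=float(chi2), p=p)
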