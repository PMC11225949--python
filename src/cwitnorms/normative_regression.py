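"""Demographic regression models on scaled scores.

The normative model predicts a subtest's scaled score from age, years of
education, and sex.  Age and education enter mean-centered (so the
intercept is the expected score of an average-aged, average-educated
man), with polynomial and interaction terms considered in a full model

    age + age^2 + age^3 + female + edu + edu^2 + edu^3
        + age*female + edu*female + age*edu

which is simplified backwards under a nested-F criterion while
respecting marginality: an interaction is never dropped after its
components, and a power never before a higher power of the same
variable.  The retained equation, its residual SD, and per-term
statistics form the normative equation used for scoring.

Equality of coefficients across subtests is tested with seemingly
unrelated regressions (one-step FGLS), whose joint coefficient
covariance yields a Z-test on the difference of two slopes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort_io import CohortTable, ParticipantRecord, Subtest

__all__ = [
    "TERM_ORDER",
    "TermKind",
    "term_kind",
    "FULL_MODEL_TERMS",
    "CenteringConstants",
    "design_row",
    "design_matrix",
    "FittedModel",
    "fit_ols",
    "SelectionStep",
    "ModelSelectionTrace",
    "select_model",
    "NormativeEquation",
    "extract_equation",
    "Diagnostics",
    "diagnostics",
    "EqualityTestResult",
    "test_equality",
    "CollinearityError",
]

# ---------------------------------------------------------------- terms

#: All terms of the full model, in canonical order.
TERM_ORDER = (
    "age",
    "age2",
    "age3",
    "edu",
    "edu2",
    "edu3",
    "female",
    "age_x_female",
    "edu_x_female",
    "age_x_edu",
)

FULL_MODEL_TERMS = TERM_ORDER

#: Marginality: a term may only be dropped while none of its dependants
#: remain in the model.
_DEPENDANTS = {
    "age": ("age2", "age3", "age_x_female", "age_x_edu"),
    "age2": ("age3",),
    "edu": ("edu2", "edu3", "edu_x_female", "age_x_edu"),
    "edu2": ("edu3",),
    "female": ("age_x_female", "edu_x_female"),
}

TermKind = str  # "interaction" | "cubic" | "quadratic" | "main"

_KIND = {
    "age_x_female": "interaction",
    "edu_x_female": "interaction",
    "age_x_edu": "interaction",
    "age3": "cubic",
    "edu3": "cubic",
    "age2": "quadratic",
    "edu2": "quadratic",
    "age": "main",
    "edu": "main",
    "female": "main",
}

#: Drop-priority of term kinds during backward simplification.
_KIND_PRIORITY = {"interaction": 0, "cubic": 1, "quadratic": 2, "main": 3}


def term_kind(term: str) -> TermKind:
    return _KIND[term]


@dataclass(frozen=True)
class CenteringConstants:
    """Means subtracted from age and education before forming terms."""

    age_mean: float = 46.2
    edu_mean: float = 15.5

    @classmethod
    def from_cohort(cls, cohort: CohortTable) -> "CenteringConstants":
        ages = [r.age for r in cohort]
        edus = [r.education for r in cohort]
        return cls(age_mean=float(np.mean(ages)), edu_mean=float(np.mean(edus)))


def _term_values(age_c: np.ndarray, edu_c: np.ndarray, female: np.ndarray) -> dict:
    return {
        "age": age_c,
        "age2": age_c**2,
        "age3": age_c**3,
        "edu": edu_c,
        "edu2": edu_c**2,
        "edu3": edu_c**3,
        "female": female,
        "age_x_female": age_c * female,
        "edu_x_female": edu_c * female,
        "age_x_edu": age_c * edu_c,
    }


def design_row(
    record: ParticipantRecord,
    terms: Sequence[str],
    centering: CenteringConstants = CenteringConstants(),
) -> np.ndarray:
    """Centered design vector (without intercept) for one participant."""
    age_c = np.array([record.age - centering.age_mean])
    edu_c = np.array([record.education - centering.edu_mean])
    female = np.array([float(record.female)])
    values = _term_values(age_c, edu_c, female)
    return np.array([values[t][0] for t in terms])


def design_matrix(
    ages: Sequence[float],
    edus: Sequence[float],
    females: Sequence[int],
    terms: Sequence[str],
    centering: CenteringConstants = CenteringConstants(),
) -> np.ndarray:
    """Design matrix with leading intercept column."""
    age_c = np.asarray(ages, dtype=float) - centering.age_mean
    edu_c = np.asarray(edus, dtype=float) - centering.edu_mean
    female = np.asarray(females, dtype=float)
    values = _term_values(age_c, edu_c, female)
    cols = [np.ones_like(age_c)] + [values[t] for t in terms]
    return np.column_stack(cols)


# ------------------------------------------------------------------ OLS


class CollinearityError(ValueError):
    """Design matrix is rank deficient; message names offending columns."""


@dataclass
class FittedModel:
    """OLS fit of scaled scores on demographic terms.

    Parameter vectors are ordered (intercept, *terms).  partial_r2 for a
    term is t^2/(t^2 + df_resid), the squared partial correlation.
    """

    terms: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    conf_int: np.ndarray  # (p, 2) at 95%
    partial_r2: np.ndarray  # per term (intercept slot = nan)
    adj_r2: float
    r2: float
    sd_residual: float
    bic: float
    df_resid: int
    nobs: int
    ssr: float
    resid: np.ndarray
    fittedvalues: np.ndarray
    cov_params: np.ndarray
    _sm_result: object = field(default=None, repr=False)

    @property
    def names(self) -> tuple[str, ...]:
        return ("intercept",) + self.terms


def fit_ols(X: np.ndarray, y: Sequence[float], terms: Sequence[str]) -> FittedModel:
    """Least-squares fit; X must carry the intercept as first column."""
    y = np.asarray(y, dtype=float)
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} rows for {X.shape[1]} columns, got {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not increase the rank when added
        names = ("intercept",) + tuple(terms)
        offenders = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                offenders.append(names[j])
            r = rj
        raise CollinearityError(f"rank-deficient design; offending columns: {offenders}")
    res = sm.OLS(y, X).fit()
    df_resid = int(res.df_resid)
    t = np.asarray(res.tvalues)
    with np.errstate(invalid="ignore"):
        pr2 = t**2 / (t**2 + df_resid)
    pr2[0] = np.nan  # intercept has no partial R^2
    sd_resid = math.sqrt(res.ssr / df_resid) if df_resid > 0 else 0.0
    return FittedModel(
        terms=tuple(terms),
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        tvalues=t,
        pvalues=np.asarray(res.pvalues),
        conf_int=np.asarray(res.conf_int()),
        partial_r2=pr2,
        adj_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        sd_residual=sd_resid,
        bic=float(res.bic),
        df_resid=df_resid,
        nobs=int(res.nobs),
        ssr=float(res.ssr),
        resid=np.asarray(res.resid),
        fittedvalues=np.asarray(res.fittedvalues),
        cov_params=np.asarray(res.cov_params()),
        _sm_result=res,
    )


def _fit_terms(
    ages, edus, females, y, terms: Sequence[str], centering: CenteringConstants
) -> FittedModel:
    X = design_matrix(ages, edus, females, terms, centering)
    return fit_ols(X, y, terms)


# ------------------------------------------------------- model selection


@dataclass(frozen=True)
class SelectionStep:
    """One attempted single-term drop during backward simplification."""

    dropped: str
    f_statistic: float
    p_value: float
    bic_before: float
    bic_after: float
    accepted: bool


@dataclass
class ModelSelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["step  term           F        p        BIC_before  BIC_after  decision"]
        for i, s in enumerate(self.steps, 1):
            lines.append(
                f"{i:>4}  {s.dropped:<13} {s.f_statistic:>8.3f} {s.p_value:>8.4f} "
                f"{s.bic_before:>11.1f} {s.bic_after:>10.1f}  "
                f"{'drop' if s.accepted else 'keep'}"
            )
        return "\n".join(lines)


def _droppable(terms: Sequence[str]) -> list[str]:
    present = set(terms)
    out = []
    for t in terms:
        deps = _DEPENDANTS.get(t, ())
        if not any(d in present for d in deps):
            out.append(t)
    return out


def _nested_f(full: FittedModel, reduced: FittedModel) -> tuple[float, float]:
    """F-test of the reduced model against the full (one dropped term)."""
    df_num = reduced.df_resid - full.df_resid
    f = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / full.df_resid)
    p = float(stats.f.sf(f, df_num, full.df_resid))
    return float(f), p


def select_model(
    cohort: CohortTable,
    subtest_scores: Mapping[str, float] | Sequence[float],
    *,
    full_terms: Sequence[str] = FULL_MODEL_TERMS,
    alpha_selection: float = 0.01,
    centering: CenteringConstants | None = None,
) -> tuple[FittedModel, ModelSelectionTrace]:
    """Backward stepwise simplification of the full demographic model.

    At each step, every droppable term (marginality respected) is scored
    by the nested F-test of its removal; among the candidates whose
    removal is supported (p >= alpha_selection), the one of lowest order
    (interactions before cubics before quadratics before mains), breaking
    ties by largest p, is dropped.  BIC is recorded at every step but
    never overrides the F-test decision.  Simplification is accepted at
    exactly p == alpha_selection.
    """
    if centering is None:
        centering = CenteringConstants.from_cohort(cohort)
    ages = [r.age for r in cohort]
    edus = [r.education for r in cohort]
    females = [r.female for r in cohort]
    if isinstance(subtest_scores, Mapping):
        y = [subtest_scores[r.id] for r in cohort]
    else:
        y = list(subtest_scores)
    terms = list(full_terms)
    current = _fit_terms(ages, edus, females, y, terms, centering)
    trace = ModelSelectionTrace()
    while terms:
        candidates = []
        for t in _droppable(terms):
            reduced_terms = [x for x in terms if x != t]
            reduced = _fit_terms(ages, edus, females, y, reduced_terms, centering)
            f, p = _nested_f(current, reduced)
            candidates.append((t, f, p, reduced))
        supported = [c for c in candidates if c[2] >= alpha_selection]
        if not supported:
            for t, f, p, reduced in candidates:
                trace.steps.append(
                    SelectionStep(t, f, p, current.bic, reduced.bic, accepted=False)
                )
            break
        t, f, p, reduced = min(
            supported, key=lambda c: (_KIND_PRIORITY[term_kind(c[0])], -c[2])
        )
        trace.steps.append(SelectionStep(t, f, p, current.bic, reduced.bic, accepted=True))
        terms.remove(t)
        current = reduced
    return current, trace


# --------------------------------------------------- normative equation


@dataclass(frozen=True)
class NormativeEquation:
    """Self-contained scoring equation for one subtest.

    predicted = intercept + sum_t coefficients[t] * term_t(centered
    demographics).  ``sd_residual`` standardizes the deviation of the
    obtained scaled score from this prediction.
    """

    subtest: Subtest
    intercept: float
    coefficients: Mapping[str, float]
    centering: CenteringConstants = CenteringConstants()
    sd_residual: float = 3.0
    term_stats: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    adj_r2: float | None = None
    n: int | None = None
    version: str = "1"

    def __post_init__(self) -> None:
        if self.sd_residual <= 0:
            raise ValueError("sd_residual must be positive")
        unknown = set(self.coefficients) - set(TERM_ORDER)
        if unknown:
            raise ValueError(f"unknown terms: {sorted(unknown)}")

    def predict(self, age: float, education: float, female: int) -> float:
        age_c = age - self.centering.age_mean
        edu_c = education - self.centering.edu_mean
        values = {
            "age": age_c,
            "age2": age_c**2,
            "age3": age_c**3,
            "edu": edu_c,
            "edu2": edu_c**2,
            "edu3": edu_c**3,
            "female": float(female),
            "age_x_female": age_c * female,
            "edu_x_female": edu_c * female,
            "age_x_edu": age_c * edu_c,
        }
        return self.intercept + sum(b * values[t] for t, b in self.coefficients.items())

    def predict_many(
        self, ages: np.ndarray, edus: np.ndarray, females: np.ndarray
    ) -> np.ndarray:
        terms = list(self.coefficients)
        X = design_matrix(ages, edus, females, terms, self.centering)
        beta = np.concatenate([[self.intercept], [self.coefficients[t] for t in terms]])
        return X @ beta

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "subtest": self.subtest.value,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "centering": {
                "age_mean": self.centering.age_mean,
                "edu_mean": self.centering.edu_mean,
            },
            "sd_residual": self.sd_residual,
            "term_stats": {k: dict(v) for k, v in self.term_stats.items()},
            "adj_r2": self.adj_r2,
            "n": self.n,
            "version": self.version,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "NormativeEquation":
        return cls(
            subtest=Subtest(data["subtest"]),
            intercept=float(data["intercept"]),
            coefficients={k: float(v) for k, v in data["coefficients"].items()},
            centering=CenteringConstants(**data["centering"]),
            sd_residual=float(data["sd_residual"]),
            term_stats=data.get("term_stats", {}),
            adj_r2=data.get("adj_r2"),
            n=data.get("n"),
            version=str(data.get("version", "1")),
        )

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeEquation":
        return cls.from_dict(json.loads(Path(path).read_text()))


def extract_equation(
    fitted: FittedModel,
    subtest: Subtest,
    centering: CenteringConstants,
    version: str = "1",
) -> NormativeEquation:
    """Package a fitted model as a self-contained normative equation."""
    stats_per_term = {}
    for i, name in enumerate(fitted.names):
        stats_per_term[name] = {
            "b": float(fitted.params[i]),
            "se": float(fitted.bse[i]),
            "t": float(fitted.tvalues[i]),
            "p": float(fitted.pvalues[i]),
            "partial_r2": float(fitted.partial_r2[i]) if i > 0 else float("nan"),
        }
    return NormativeEquation(
        subtest=subtest,
        intercept=float(fitted.params[0]),
        coefficients={t: float(b) for t, b in zip(fitted.terms, fitted.params[1:])},
        centering=centering,
        sd_residual=fitted.sd_residual,
        term_stats=stats_per_term,
        adj_r2=fitted.adj_r2,
        n=fitted.nobs,
        version=version,
    )


# ------------------------------------------------------------ diagnostics


@dataclass
class Diagnostics:
    """Per-observation residual diagnostics; nothing is auto-deleted."""

    standardized_residuals: np.ndarray
    cooks_distance: np.ndarray
    abs_resid_vs_fitted_r: float  # heteroscedasticity descriptive


def diagnostics(fitted: FittedModel) -> Diagnostics:
    if fitted.sd_residual < 1e-10:
        # perfect fit: residual-scaled influence measures are all zero
        zeros = np.zeros(fitted.nobs)
        return Diagnostics(
            standardized_residuals=zeros,
            cooks_distance=zeros.copy(),
            abs_resid_vs_fitted_r=0.0,
        )
    infl = fitted._sm_result.get_influence()  # type: ignore[union-attr]
    cooks = np.asarray(infl.cooks_distance[0])
    std_resid = np.asarray(infl.resid_studentized_internal)
    if np.ptp(fitted.fittedvalues) > 0 and np.ptp(np.abs(fitted.resid)) > 0:
        r = float(np.corrcoef(np.abs(fitted.resid), fitted.fittedvalues)[0, 1])
    else:
        r = 0.0
    return Diagnostics(
        standardized_residuals=std_resid,
        cooks_distance=cooks,
        abs_resid_vs_fitted_r=r,
    )


# ------------------------------------- SUR / equality of coefficients


@dataclass(frozen=True)
class EqualityTestResult:
    """Z-test of b1 == b2 for one term across two subtest equations."""

    subtest_a: Subtest
    subtest_b: Subtest
    term: str
    b1: float
    b2: float
    diff: float
    se_diff: float
    z: float
    p: float


def _sur_fgls(
    Xs: Sequence[np.ndarray], ys: Sequence[np.ndarray]
) -> tuple[list[np.ndarray], np.ndarray]:
    """One-step FGLS for a two-equation SUR system on common participants.

    Per-equation OLS residuals estimate the cross-equation residual
    covariance (denominator n); the stacked system is then re-estimated
    by GLS.  Returns per-equation coefficient vectors and the joint
    coefficient covariance matrix.
    """
    n = Xs[0].shape[0]
    resids = []
    for X, y in zip(Xs, ys):
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resids.append(y - X @ beta)
    sigma = np.cov(np.vstack(resids), bias=True)  # 2 x 2, denominator n
    # perfectly correlated residuals (e.g. identical responses) make the
    # covariance singular; a tiny ridge keeps the GLS step well-posed
    if np.linalg.det(sigma) < 1e-12 * max(np.prod(np.diag(sigma)), 1e-300):
        sigma = sigma + 1e-8 * np.trace(sigma) * np.eye(sigma.shape[0])
    sigma_inv = np.linalg.inv(sigma)
    ks = [X.shape[1] for X in Xs]
    m = len(Xs)
    A = np.zeros((sum(ks), sum(ks)))
    b = np.zeros(sum(ks))
    offs = np.concatenate([[0], np.cumsum(ks)])
    for i in range(m):
        for j in range(m):
            A[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = sigma_inv[i, j] * (Xs[i].T @ Xs[j])
        b[offs[i]:offs[i + 1]] = sum(sigma_inv[i, j] * (Xs[i].T @ ys[j]) for j in range(m))
    cov = np.linalg.inv(A)
    beta_all = cov @ b
    betas = [beta_all[offs[i]:offs[i + 1]] for i in range(m)]
    return betas, cov


def test_equality(
    cohort: CohortTable,
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    terms_a: Sequence[str],
    terms_b: Sequence[str],
    term: str,
    *,
    subtest_a: Subtest = Subtest.CWIT1,
    subtest_b: Subtest = Subtest.CWIT2,
    centering: CenteringConstants | None = None,
) -> EqualityTestResult:
    """Test equality of a coefficient across two subtests' equations.

    Both equations are estimated jointly as seemingly unrelated
    regressions on the same participants; the Z statistic uses the
    covariance-adjusted standard error of the difference.
    """
    if term not in terms_a or term not in terms_b:
        raise ValueError(f"term {term!r} must appear in both models")
    if centering is None:
        centering = CenteringConstants.from_cohort(cohort)
    ages = [r.age for r in cohort]
    edus = [r.education for r in cohort]
    females = [r.female for r in cohort]
    Xa = design_matrix(ages, edus, females, terms_a, centering)
    Xb = design_matrix(ages, edus, females, terms_b, centering)
    ya = np.asarray(scores_a, dtype=float)
    yb = np.asarray(scores_b, dtype=float)
    if ya.shape[0] != yb.shape[0] or ya.shape[0] != Xa.shape[0]:
        raise ValueError("both responses must be observed on the same participants")
    betas, cov = _sur_fgls([Xa, Xb], [ya, yb])
    ia = 1 + list(terms_a).index(term)  # +1 for intercept
    ib = Xa.shape[1] + 1 + list(terms_b).index(term)
    b1 = float(betas[0][ia])
    b2 = float(betas[1][ib - Xa.shape[1]])
    var = cov[ia, ia] + cov[ib, ib] - 2.0 * cov[ia, ib]
    se = math.sqrt(max(var, 0.0))
    diff = b1 - b2
    z = diff / se if se > 0 else 0.0
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return EqualityTestResult(
        subtest_a=subtest_a,
        subtest_b=subtest_b,
        term=term,
        b1=b1,
        b2=b2,
        diff=diff,
        se_diff=se,
        z=z,
        p=p,
    )
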