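"""Synthetic cohorts with the demographic and effect structure of the
Norwegian normative sample.

The study data are restricted, so every downstream stage is exercised on
simulated cohorts built to the published marginals: n = 1011 healthy
adults aged 20-85 (mean 46.2, SD 19.4, with a thin middle-age band),
7-23 years of education (mean 15.5, SD 2.9), 66.8% female.  Completion
times are generated by inverting the published machinery — a latent
scaled score is drawn from the subtest's normative equation plus
Gaussian residual, rounded and clipped to 1-19, and a raw time is drawn
uniformly within that scaled score's conversion bin — which guarantees
that re-scoring a generated raw time recovers the generating scaled
score exactly.

Error counts follow a hurdle model (exact probability of making any
error; zero-truncated negative binomial for how many), calibrated once
against the published cumulative error percentages.  Retest data impose
a latent bivariate-normal correlation chosen so the ICC observed on
discretized T-scores hits the target despite rounding attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import (
    CohortTable,
    ERROR_SUBTESTS,
    ParticipantRecord,
    Sex,
    Subtest,
)
from .normative_regression import NormativeEquation
from .norm_scoring import NormSet, norwegian_norms
from .scaled_scores import ConversionTable, SCALED_MAX, SCALED_MIN

__all__ = [
    "AgeMixture",
    "EducationModel",
    "ErrorModel",
    "RetestSpec",
    "SimulationSpec",
    "SyntheticCohort",
    "gen_demographics",
    "gen_cwit_times",
    "gen_errors",
    "gen_retest",
    "simulate_cohort",
]


@dataclass(frozen=True)
class AgeMixture:
    """Two truncated normals on [20, 85] emulating the bimodal age profile.

    The normative sample is thin in middle age; a young component near 30
    and a broad older component near 68 reproduce the published overall
    mean (46.2) and SD (19.4) exactly at the default parameters.
    """

    mean1: float = 29.5103
    sd1: float = 3.9025
    mean2: float = 68.1025
    sd2: float = 17.8580
    weight1: float = 0.5
    low: float = 20.0
    high: float = 85.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight1 <= 1.0):
            raise ValueError("weight must be a probability")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("SDs must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.random(n) < self.weight1
        out = np.empty(n)
        for is_first, mean, sd in ((True, self.mean1, self.sd1),
                                   (False, self.mean2, self.sd2)):
            idx = np.flatnonzero(comp == is_first)
            a, b = (self.low - mean) / sd, (self.high - mean) / sd
            u = rng.random(idx.size)
            # inverse-CDF sampling keeps the draw deterministic per index
            out[idx] = stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
        return out


@dataclass(frozen=True)
class EducationModel:
    """Discrete truncated normal on [7, 23] years of education."""

    mean: float = 15.5
    sd: float = 2.9
    low: int = 7
    high: int = 23

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("SD must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n, dtype=int)
        remaining = np.arange(n)
        while remaining.size:
            draw = np.rint(rng.normal(self.mean, self.sd, remaining.size)).astype(int)
            ok = (draw >= self.low) & (draw <= self.high)
            out[remaining[ok]] = draw[ok]
            remaining = remaining[~ok]
        return out


@dataclass(frozen=True)
class ErrorModel:
    """Hurdle negative binomial for one subtest's total error count.

    With probability 1 - p_any the count is zero; otherwise it is drawn
    from NB(r, p) conditioned on being positive.  Defaults were fitted
    once by least squares to the published cumulative error percentages
    and are independent of demographics by construction.
    """

    p_any: float
    nb_r: float
    nb_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_any <= 1.0):
            raise ValueError("p_any must be a probability")
        if self.nb_r <= 0 or not (0.0 < self.nb_p < 1.0):
            raise ValueError("invalid negative-binomial parameters")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.zeros(n, dtype=int)
        positive = np.flatnonzero(rng.random(n) < self.p_any)
        remaining = positive
        while remaining.size:
            # gamma-Poisson mixture; redraw zeros (truncation at >= 1)
            lam = rng.gamma(self.nb_r, (1.0 - self.nb_p) / self.nb_p, remaining.size)
            draw = rng.poisson(lam)
            ok = draw >= 1
            out[remaining[ok]] = draw[ok]
            remaining = remaining[~ok]
        return out


#: Per-subtest error models calibrated to the published cumulative
#: percentages (51.4/23.2/11.1/5.2/2.8/1.2 at k = 1..6 on CWIT-3 and
#: 55.4/26.5/12.9/6.3/3.2/1.5 on CWIT-4).
DEFAULT_ERROR_MODELS: dict[Subtest, ErrorModel] = {
    Subtest.CWIT3: ErrorModel(p_any=0.514, nb_r=0.65449019, nb_p=0.47586802),
    Subtest.CWIT4: ErrorModel(p_any=0.554, nb_r=0.85952467, nb_p=0.49378932),
}


@dataclass(frozen=True)
class RetestSpec:
    """Retest generation: target ICCs, practice effect, interval law."""

    target_icc: Mapping[Subtest, float] = field(
        default_factory=lambda: {
            Subtest.CWIT1: 0.68,
            Subtest.CWIT2: 0.68,
            Subtest.CWIT3: 0.76,
            Subtest.CWIT4: 0.70,
        }
    )
    practice_effect: float = 0.0  # mean scaled-score change at follow-up
    interval_mean: float = 3.4
    interval_sd: float = 0.9
    interval_low: float = 1.0
    interval_high: float = 5.0
    p_over_limit: float = 0.0  # fraction of intervals beyond the high bound

    def __post_init__(self) -> None:
        for st, icc in self.target_icc.items():
            if not (0.0 < icc < 1.0):
                raise ValueError(f"target ICC for {st} must be in (0, 1), got {icc}")
        if not (0.0 <= self.p_over_limit <= 1.0):
            raise ValueError("p_over_limit must be a probability")


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to generate a cohort deterministically."""

    n: int = 1011
    age_model: AgeMixture = AgeMixture()
    education_model: EducationModel = EducationModel()
    p_female: float = 0.668
    normset: NormSet | None = None  # defaults to the packaged Norwegian norms
    error_models: Mapping[Subtest, ErrorModel] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_MODELS)
    )
    retest: RetestSpec = RetestSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not (0.0 <= self.p_female <= 1.0):
            raise ValueError("p_female must be a probability")

    def resolved_normset(self) -> NormSet:
        return self.normset if self.normset is not None else norwegian_norms()


@dataclass
class SyntheticCohort:
    """Generated cohort plus the latent continuous scaled scores.

    The latent frame (one column per subtest) exists for oracle tests
    only — real data never expose it.
    """

    cohort: CohortTable
    latent: pd.DataFrame


def gen_demographics(spec: SimulationSpec) -> CohortTable:
    """Sample ids, ages, education, and sex; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    ages = spec.age_model.sample(spec.n, rng)
    edus = spec.education_model.sample(spec.n, rng)
    female = rng.random(spec.n) < spec.p_female
    records = [
        ParticipantRecord(
            id=f"S{i:06d}",
            age=float(round(a, 1)),
            education=int(e),
            sex=Sex.FEMALE if f else Sex.MALE,
        )
        for i, (a, e, f) in enumerate(zip(ages, edus, female))
    ]
    return CohortTable(records=records, provenance=f"synthetic(seed={spec.seed})")


def _nearest_available_scaled(table: ConversionTable, s: int) -> int:
    """Snap a scaled score to the nearest value the table can represent.

    Ties break toward the middle of the scale (10): tables with gaps at
    extreme scaled scores push an unrepresentable value inward.
    """
    avail = table.available_scaled
    if s in avail:
        return s
    return min(avail, key=lambda a: (abs(a - s), abs(a - 10)))


def _raw_from_scaled(
    table: ConversionTable, scaled: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw integer raw times uniformly within each scaled score's bin.

    Open-ended extreme bins get a geometric tail (p = 0.5) beyond the
    closed boundary.
    """
    raw = np.empty(scaled.size, dtype=int)
    for s in np.unique(scaled):
        b = table.bin_for_scaled(int(s))
        idx = np.flatnonzero(scaled == s)
        if b.low is not None and b.high is not None:
            raw[idx] = rng.integers(b.low, b.high + 1, idx.size)
        elif b.low is None:  # fastest bin, open below
            assert b.high is not None
            tail = rng.geometric(0.5, idx.size) - 1
            raw[idx] = np.maximum(b.high - tail, 1)
        else:  # slowest bin, open above
            tail = rng.geometric(0.5, idx.size) - 1
            raw[idx] = b.low + tail
    return raw


def gen_cwit_times(
    cohort: CohortTable,
    normset: NormSet | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate completion times consistent with a norm set.

    Latent scaled = predicted(demographics) + N(0, sd_residual); the
    integer scaled score is the clipped round of the latent (snapped to a
    representable value where the conversion table has gaps), and the raw
    time is drawn within that score's bin, so re-scoring the raw time
    reproduces the integer scaled score exactly.
    """
    normset = normset or norwegian_norms()
    rng = np.random.default_rng(seed)
    ages = np.asarray([r.age for r in cohort], dtype=float)
    edus = np.asarray([r.education for r in cohort], dtype=float)
    females = np.asarray([r.female for r in cohort], dtype=float)
    latent = {}
    raw_by_subtest = {}
    for st in normset.subtests:
        eq = normset.equations[st]
        table = normset.tables[st]
        predicted = eq.predict_many(ages, edus, females)
        y_star = predicted + rng.normal(0.0, eq.sd_residual, len(cohort))
        s = np.clip(np.rint(y_star).astype(int), SCALED_MIN, SCALED_MAX)
        snapped = np.asarray([_nearest_available_scaled(table, int(v)) for v in s])
        raw_by_subtest[st] = _raw_from_scaled(table, snapped, rng)
        latent[st.value] = y_star
    records = []
    for i, r in enumerate(cohort):
        times = {st: int(raw_by_subtest[st][i]) for st in raw_by_subtest}
        records.append(replace(r, times=times))
    return SyntheticCohort(
        cohort=CohortTable(records=records, provenance=cohort.provenance),
        latent=pd.DataFrame(latent, index=[r.id for r in cohort]),
    )


def gen_errors(
    cohort: CohortTable,
    error_models: Mapping[Subtest, ErrorModel] | None = None,
    seed: int = 0,
) -> CohortTable:
    """Attach error counts drawn from the calibrated hurdle models."""
    models = dict(error_models or DEFAULT_ERROR_MODELS)
    rng = np.random.default_rng(seed)
    draws = {st: m.sample(len(cohort), rng) for st, m in models.items()}
    records = [
        replace(r, errors={st: int(draws[st][i]) for st in draws})
        for i, r in enumerate(cohort)
    ]
    return CohortTable(records=records, provenance=cohort.provenance)


def gen_retest(
    cohort: CohortTable,
    retest: RetestSpec | None = None,
    normset: NormSet | None = None,
    seed: int = 0,
) -> CohortTable:
    """Generate follow-up times and retest intervals (longitudinal schema).

    Follow-up latent scaled scores correlate with the baseline latent at
    a level inflated for discretization, so the ICC observed on scored
    T-scores matches the target.  Intervals are truncated-normal on
    [interval_low, interval_high]; a configurable fraction lies beyond
    the high bound to exercise the exclusion filter.
    """
    retest = retest or RetestSpec()
    normset = normset or norwegian_norms()
    rng = np.random.default_rng(seed)
    ages = np.asarray([r.age for r in cohort], dtype=float)
    edus = np.asarray([r.education for r in cohort], dtype=float)
    females = np.asarray([r.female for r in cohort], dtype=float)
    if any(not r.times for r in cohort):
        raise ValueError("baseline times must be present before generating retest data")
    fu_by_subtest = {}
    for st in normset.subtests:
        if st not in retest.target_icc:
            continue
        eq = normset.equations[st]
        table = normset.tables[st]
        predicted = eq.predict_many(ages, edus, females)
        baseline_raw = np.asarray([r.times[st] for r in cohort], dtype=float)
        baseline_scaled = np.asarray([table.lookup(t) for t in baseline_raw], dtype=float)
        base_resid = baseline_scaled - predicted
        sd = eq.sd_residual
        # inflate the latent correlation to undo rounding attenuation
        # (rounding to integer scaled scores adds variance 1/12)
        target = retest.target_icc[st]
        rho = min(target * (sd**2 + 1.0 / 12.0) / sd**2, 0.999)
        noise = rng.normal(0.0, sd * math.sqrt(max(1.0 - rho**2, 0.0)), len(cohort))
        fu_latent = predicted + retest.practice_effect + rho * base_resid + noise
        s = np.clip(np.rint(fu_latent).astype(int), SCALED_MIN, SCALED_MAX)
        snapped = np.asarray([_nearest_available_scaled(table, int(v)) for v in s])
        fu_by_subtest[st] = _raw_from_scaled(table, snapped, rng)
    a, b = (
        (retest.interval_low - retest.interval_mean) / retest.interval_sd,
        (retest.interval_high - retest.interval_mean) / retest.interval_sd,
    )
    intervals = stats.truncnorm.ppf(
        rng.random(len(cohort)), a, b, loc=retest.interval_mean, scale=retest.interval_sd
    )
    over = rng.random(len(cohort)) < retest.p_over_limit
    intervals = np.where(
        over, retest.interval_high + rng.random(len(cohort)) * 2.0, intervals
    )
    records = []
    for i, r in enumerate(cohort):
        fu = {st: int(fu_by_subtest[st][i]) for st in fu_by_subtest}
        records.append(
            replace(
                r,
                interval_years=float(round(intervals[i], 2)),
                times_followup=fu,
            )
        )
    return CohortTable(records=records, provenance=cohort.provenance)


def simulate_cohort(spec: SimulationSpec, *, with_retest: bool = False) -> SyntheticCohort:
    """Full generation chain: demographics, times, errors, optional retest.

    Stage seeds are derived from ``spec.seed`` so the whole cohort is a
    deterministic function of the spec.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_demo, s_times, s_err, s_retest = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )
    demo = gen_demographics(replace(spec, seed=s_demo))
    normset = spec.resolved_normset()
    synth = gen_cwit_times(demo, normset, seed=s_times)
    cohort = gen_errors(synth.cohort, spec.error_models, seed=s_err)
    if with_retest:
        cohort = gen_retest(cohort, spec.retest, normset, seed=s_retest)
    return SyntheticCohort(cohort=cohort, latent=synth.latent)
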