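"""The norm calculator: raw time + demographics -> scaled, Z, and T.

Scoring chains three steps.  The raw completion time is converted to an
obtained scaled score through the subtest's conversion table; the
normative equation predicts the scaled score expected for the person's
age, education, and sex; and the deviation is standardized by the
equation's residual SD:

    Z = (obtained scaled - predicted scaled) / SD_residual
    T = 10 * Z + 50

Full precision is carried internally; the conventional clinical display
rounds the predicted score and Z to two decimals and T to the nearest
integer (halves away from zero).

The published Norwegian norms (n = 1011, ages 20-85) ship with the
package as a versioned, immutable transcription and are returned by
:func:`norwegian_norms`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortTable, Subtest
from .normative_regression import CenteringConstants, NormativeEquation
from .scaled_scores import ConversionTable, ScaledBin, round_half_away

__all__ = [
    "NormScore",
    "NormSet",
    "predict_scaled",
    "score",
    "score_batch",
    "norwegian_norms",
]


@dataclass(frozen=True)
class NormScore:
    """Normed result for one person on one subtest."""

    subtest: Subtest
    raw: int
    obtained_scaled: int
    predicted_scaled: float
    z: float
    t: float
    warnings: tuple[str, ...] = ()

    @property
    def t_rounded(self) -> int:
        return round_half_away(self.t)

    @property
    def percentile(self) -> float:
        """Normal-distribution percentile equivalent of the T-score."""
        return 100.0 * float(stats.norm.cdf(self.z))

    def display(self) -> dict:
        """Values at conventional clinical precision."""
        return {
            "subtest": self.subtest.value,
            "raw": self.raw,
            "obtained_scaled": self.obtained_scaled,
            "predicted_scaled": round(self.predicted_scaled, 2),
            "z": round(self.z, 2),
            "t": self.t_rounded,
            "percentile": round(self.percentile, 1),
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class NormSet:
    """A label, a normative equation, and a conversion table per subtest."""

    label: str
    equations: Mapping[Subtest, NormativeEquation]
    tables: Mapping[Subtest, ConversionTable]
    version: str = "1"

    def __post_init__(self) -> None:
        missing = set(self.equations) - set(self.tables)
        if missing:
            raise ValueError(f"equations without conversion tables: {sorted(missing)}")

    @property
    def subtests(self) -> tuple[Subtest, ...]:
        return tuple(st for st in Subtest if st in self.equations)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "version": self.version,
            "equations": {st.value: eq.to_dict() for st, eq in self.equations.items()},
            "tables": {st.value: tb.to_dict() for st, tb in self.tables.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "NormSet":
        return cls(
            label=data["label"],
            version=str(data.get("version", "1")),
            equations={
                Subtest(k): NormativeEquation.from_dict(v)
                for k, v in data["equations"].items()
            },
            tables={
                Subtest(k): ConversionTable.from_dict(v) for k, v in data["tables"].items()
            },
        )

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "NormSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def predict_scaled(
    eq: NormativeEquation, age: float, education: float, female: int
) -> tuple[float, tuple[str, ...]]:
    """Predicted scaled score with advisory out-of-range warnings.

    Scoring proceeds outside the norms' demographic range (ages 20-85);
    the warning flags that the prediction extrapolates.
    """
    warnings: list[str] = []
    if not (20.0 <= age <= 85.0):
        warnings.append(f"age {age:g} outside the normative range 20-85; extrapolating")
    if not (0 <= education <= 30):
        warnings.append(f"education {education:g} outside the plausible range 0-30")
    return eq.predict(age, education, female), tuple(warnings)


def score(
    normset: NormSet,
    subtest: Subtest,
    raw: int,
    *,
    age: float,
    education: float,
    female: int,
) -> NormScore:
    """Score one raw completion time against a norm set."""
    if raw <= 0:
        raise ValueError(f"raw time must be positive, got {raw}")
    if subtest not in normset.equations:
        raise KeyError(f"norm set {normset.label!r} has no equation for {subtest}")
    eq = normset.equations[subtest]
    table = normset.tables[subtest]
    obtained = table.lookup(raw)
    predicted, warnings = predict_scaled(eq, age, education, female)
    z = (obtained - predicted) / eq.sd_residual
    t = 10.0 * z + 50.0
    return NormScore(
        subtest=subtest,
        raw=int(raw),
        obtained_scaled=obtained,
        predicted_scaled=predicted,
        z=z,
        t=t,
        warnings=warnings,
    )


def score_batch(
    normset: NormSet,
    cohort: CohortTable,
    subtests: Sequence[Subtest] | None = None,
    *,
    followup: bool = False,
) -> pd.DataFrame:
    """Score every available (person, subtest) pair of a cohort.

    Missing raw times yield no row (absent scores, never zeros).  With
    ``followup=True`` the follow-up times of a longitudinal cohort are
    scored instead of the baseline times.
    """
    subtests = list(subtests or normset.subtests)
    rows = []
    for r in cohort:
        times = r.times_followup if followup else r.times
        for st in subtests:
            if st not in times or st not in normset.equations:
                continue
            s = score(
                normset, st, times[st], age=r.age, education=r.education, female=r.female
            )
            rows.append(
                {
                    "id": r.id,
                    "subtest": st.value,
                    "raw": s.raw,
                    "obtained_scaled": s.obtained_scaled,
                    "predicted_scaled": s.predicted_scaled,
                    "z": s.z,
                    "t": s.t,
                    "t_rounded": s.t_rounded,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "subtest",
            "raw",
            "obtained_scaled",
            "predicted_scaled",
            "z",
            "t",
            "t_rounded",
        ],
    )


# --------------------------------------------------- Norwegian norms

# Raw-time bins (inclusive integer seconds, fastest first) per subtest.
# CWIT-2 has no raw range at scaled 17 and 19: its raw distribution is so
# tight that those percentile bands fall between adjacent integer times.
_NORWEGIAN_BINS: dict[Subtest, list[tuple[int | None, int | None, int]]] = {
    Subtest.CWIT1: [
        (None, 18, 19), (19, 19, 18), (20, 20, 17), (21, 21, 16), (22, 22, 15),
        (23, 24, 14), (25, 25, 13), (26, 26, 12), (27, 28, 11), (29, 30, 10),
        (31, 32, 9), (33, 34, 8), (35, 36, 7), (37, 39, 6), (40, 41, 5),
        (42, 45, 4), (46, 47, 3), (48, 55, 2), (56, None, 1),
    ],
    Subtest.CWIT2: [
        (None, 14, 18), (15, 15, 16), (16, 16, 15), (17, 17, 14), (18, 18, 13),
        (19, 19, 12), (20, 20, 11), (21, 22, 10), (23, 23, 9), (24, 24, 8),
        (25, 26, 7), (27, 27, 6), (28, 30, 5), (31, 33, 4), (34, 36, 3),
        (37, 51, 2), (52, None, 1),
    ],
    Subtest.CWIT3: [
        (None, 26, 19), (27, 30, 18), (31, 32, 17), (33, 34, 16), (35, 36, 15),
        (37, 39, 14), (40, 41, 13), (42, 44, 12), (45, 48, 11), (49, 52, 10),
        (53, 57, 9), (58, 62, 8), (63, 68, 7), (69, 76, 6), (77, 84, 5),
        (85, 98, 4), (99, 113, 3), (114, 129, 2), (130, None, 1),
    ],
    Subtest.CWIT4: [
        (None, 30, 19), (31, 33, 18), (34, 36, 17), (37, 38, 16), (39, 41, 15),
        (42, 44, 14), (45, 47, 13), (48, 50, 12), (51, 54, 11), (55, 59, 10),
        (60, 64, 9), (65, 70, 8), (71, 77, 7), (78, 87, 6), (88, 100, 5),
        (101, 116, 4), (117, 132, 3), (133, 167, 2), (168, None, 1),
    ],
}

# Percentile anchors as printed alongside the scaled scores.
_NORWEGIAN_ANCHORS: dict[int, float] = {
    1: 0.1, 2: 0.4, 3: 1, 4: 2, 5: 5, 6: 9, 7: 16, 8: 25, 9: 37, 10: 50,
    11: 63, 12: 75, 13: 84, 14: 91, 15: 95, 16: 98, 17: 99, 18: 99.6, 19: 99.9,
}

_NORWEGIAN_CENTERING = CenteringConstants(age_mean=46.2, edu_mean=15.5)

# Published equations: intercept, coefficients (scaled-score units per
# centered-predictor unit), residual SD, adjusted R^2 (n = 1011).
_NORWEGIAN_EQUATIONS: dict[Subtest, dict] = {
    Subtest.CWIT1: {
        "intercept": 9.863,
        "coefficients": {"age": -0.049, "age2": -0.001, "female": 0.825},
        "sd_residual": 2.775,
        "adj_r2": 0.155,
    },
    Subtest.CWIT2: {
        "intercept": 10.217,
        "coefficients": {"age": -0.019, "age2": -0.001},
        "sd_residual": 2.797,
        "adj_r2": 0.031,
    },
    Subtest.CWIT3: {
        "intercept": 10.182,
        "coefficients": {"age": -0.073, "age2": -0.001, "edu": 0.078, "female": 0.454},
        "sd_residual": 2.546,
        "adj_r2": 0.291,
    },
    Subtest.CWIT4: {
        "intercept": 10.561,
        "coefficients": {"age": -0.063, "age2": -0.002, "edu": 0.098},
        "sd_residual": 2.574,
        "adj_r2": 0.250,
    },
}

_norwegian_cache: NormSet | None = None


def norwegian_norms() -> NormSet:
    """The packaged Norwegian CWIT norms (ages 20-85, n = 1011)."""
    global _norwegian_cache
    if _norwegian_cache is None:
        tables = {}
        for st, bins in _NORWEGIAN_BINS.items():
            scaled_present = {s for _, _, s in bins}
            tables[st] = ConversionTable(
                subtest=st,
                bins=tuple(ScaledBin(lo, hi, s) for lo, hi, s in bins),
                anchors={s: p for s, p in _NORWEGIAN_ANCHORS.items() if s in scaled_present},
            )
        equations = {
            st: NormativeEquation(
                subtest=st,
                intercept=spec["intercept"],
                coefficients=spec["coefficients"],
                centering=_NORWEGIAN_CENTERING,
                sd_residual=spec["sd_residual"],
                adj_r2=spec["adj_r2"],
                n=1011,
                version="published-2024",
            )
            for st, spec in _NORWEGIAN_EQUATIONS.items()
        }
        _norwegian_cache = NormSet(
            label="norwegian",
            equations=equations,
            tables=tables,
            version="published-2024",
        )
    return _norwegian_cache
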