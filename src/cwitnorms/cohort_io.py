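"""Cohort schemas, CSV readers/writers, and run configuration.

The package works on cohort tables of healthy adults with demographics
(age in years, education in completed years, sex) and Color-Word
Interference Test outcomes: completion times in seconds on the four
subtests (CWIT-1 color naming, CWIT-2 word reading, CWIT-3 inhibition,
CWIT-4 inhibition/switching) and total error counts on CWIT-3/4.

Serialized form is plain CSV (comma separator, UTF-8, mandatory header,
"." decimal).  Missing optional cells are empty strings, never sentinel
numbers: a missing error count is distinct from zero errors.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("cwitnorms")

__all__ = [
    "Subtest",
    "Sex",
    "ParticipantRecord",
    "CohortTable",
    "RunConfig",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "NORM_AGE_MIN",
    "NORM_AGE_MAX",
]

# Inclusion bounds of the normative sample; records outside are rejected
# when a cohort is read for norm building.
NORM_AGE_MIN = 20.0
NORM_AGE_MAX = 85.0

EDUCATION_MIN = 0
EDUCATION_MAX = 30


class Subtest(str, enum.Enum):
    """The four CWIT conditions."""

    CWIT1 = "CWIT1"  # color naming
    CWIT2 = "CWIT2"  # word reading
    CWIT3 = "CWIT3"  # inhibition (classic Stroop)
    CWIT4 = "CWIT4"  # inhibition/switching

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Subtests for which error counts are recorded.
ERROR_SUBTESTS = (Subtest.CWIT3, Subtest.CWIT4)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @property
    def numeric(self) -> int:
        """Numeric coding used throughout: 0 = male, 1 = female."""
        return 0 if self is Sex.MALE else 1

    @classmethod
    def parse(cls, value: object) -> "Sex":
        """Parse heterogeneous clinical codings: {male, female, m, f, 0, 1}."""
        if isinstance(value, Sex):
            return value
        text = str(value).strip().lower()
        if text in {"male", "m", "0", "men", "man"}:
            return cls.MALE
        if text in {"female", "f", "1", "women", "woman"}:
            return cls.FEMALE
        raise ValueError(f"cannot parse sex value {value!r}")


class SchemaError(ValueError):
    """Header or column layout does not match the expected schema."""


class CohortValidationError(ValueError):
    """One or more rows violate record invariants; message is row-indexed."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: demographics plus CWIT raw outcomes.

    ``times`` maps a subtest to completion time in whole seconds;
    ``errors`` maps CWIT-3/4 to total (corrected + uncorrected) error
    counts.  Either mapping may be partial — missingness is preserved.
    """

    id: str
    age: float
    education: int
    sex: Sex
    times: Mapping[Subtest, int] = field(default_factory=dict)
    errors: Mapping[Subtest, int] = field(default_factory=dict)
    mmse: int | None = None
    # longitudinal extras (None on cross-sectional records)
    interval_years: float | None = None
    times_followup: Mapping[Subtest, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (EDUCATION_MIN <= self.education <= EDUCATION_MAX):
            raise ValueError(
                f"education {self.education} outside [{EDUCATION_MIN}, {EDUCATION_MAX}]"
            )
        if self.age < 0:
            raise ValueError(f"negative age {self.age}")
        for label, mapping in (("time", self.times), ("follow-up time", self.times_followup)):
            for st, v in mapping.items():
                if v <= 0:
                    raise ValueError(f"{label} for {st} must be positive, got {v}")
        for st, v in self.errors.items():
            if st not in ERROR_SUBTESTS:
                raise ValueError(f"errors are only recorded on CWIT-3/4, got {st}")
            if v < 0:
                raise ValueError(f"negative error count {v}")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE {self.mmse} outside [0, 30]")
        if self.interval_years is not None and self.interval_years <= 0:
            raise ValueError(f"retest interval must be positive, got {self.interval_years}")

    @property
    def female(self) -> int:
        return self.sex.numeric

    def in_norm_age_range(self) -> bool:
        return NORM_AGE_MIN <= self.age <= NORM_AGE_MAX


@dataclass
class CohortTable:
    """Ordered collection of participant records with unique ids."""

    records: list[ParticipantRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate participant ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)

    def to_frame(self, schema: str = "cross_sectional") -> pd.DataFrame:
        """Tabular view with the serialized column layout (NaN = missing)."""
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "id": r.id,
                "age": r.age,
                "education": r.education,
                "sex": r.sex.value,
            }
            for st in Subtest:
                row[f"{st.value.lower()}_time"] = r.times.get(st, math.nan)
            for st in ERROR_SUBTESTS:
                row[f"{st.value.lower()}_errors"] = r.errors.get(st, math.nan)
            row["mmse"] = math.nan if r.mmse is None else r.mmse
            if schema == "longitudinal":
                row["interval_years"] = (
                    math.nan if r.interval_years is None else r.interval_years
                )
                for st in Subtest:
                    row[f"{st.value.lower()}_time_fu"] = r.times_followup.get(st, math.nan)
            rows.append(row)
        return pd.DataFrame(rows, columns=_columns(schema))


_BASE_COLUMNS = (
    ["id", "age", "education", "sex"]
    + [f"{st.value.lower()}_time" for st in Subtest]
    + [f"{st.value.lower()}_errors" for st in ERROR_SUBTESTS]
    + ["mmse"]
)


def _columns(schema: str) -> list[str]:
    if schema == "cross_sectional":
        return list(_BASE_COLUMNS)
    if schema == "longitudinal":
        return list(_BASE_COLUMNS) + ["interval_years"] + [
            f"{st.value.lower()}_time_fu" for st in Subtest
        ]
    raise SchemaError(f"unknown schema {schema!r}")


def _cell_int(value: object, what: str, row: int) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise CohortValidationError(f"row {row}: non-numeric {what}: {value!r}") from None
    if not f.is_integer():
        raise CohortValidationError(f"row {row}: {what} must be an integer, got {value!r}")
    return int(f)


def _cell_float(value: object, what: str, row: int) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortValidationError(f"row {row}: non-numeric {what}: {value!r}") from None


def read_cohort(
    path: str | Path,
    schema: str = "cross_sectional",
    *,
    for_norm_building: bool = False,
    provenance: str | None = None,
) -> CohortTable:
    """Read and validate a cohort CSV.

    With ``for_norm_building=True`` the age inclusion criterion of the
    normative sample (20-85 years) is enforced and out-of-range rows are
    rejected with row-indexed messages.  Missing optional cells (times,
    errors, MMSE) become absent values.
    """
    path = Path(path)
    expected = _columns(schema)
    frame = pd.read_csv(path, dtype={"id": str})
    if list(frame.columns) != expected:
        raise SchemaError(
            f"{path.name}: header {list(frame.columns)} does not match "
            f"{schema} schema {expected}"
        )
    records: list[ParticipantRecord] = []
    problems: list[str] = []
    for i, raw in enumerate(frame.to_dict("records")):
        rownum = i + 2  # 1-based, after header
        try:
            age = _cell_float(raw["age"], "age", rownum)
            edu = _cell_int(raw["education"], "education", rownum)
            if age is None or edu is None or raw["id"] is None or pd.isna(raw["sex"]):
                raise CohortValidationError(
                    f"row {rownum}: id, age, education and sex are required"
                )
            if for_norm_building and not (NORM_AGE_MIN <= age <= NORM_AGE_MAX):
                raise CohortValidationError(
                    f"row {rownum}: age {age} outside normative range "
                    f"[{NORM_AGE_MIN:g}, {NORM_AGE_MAX:g}]"
                )
            times = {}
            for st in Subtest:
                v = _cell_int(raw[f"{st.value.lower()}_time"], f"{st} time", rownum)
                if v is not None:
                    times[st] = v
            errors = {}
            for st in ERROR_SUBTESTS:
                v = _cell_int(raw[f"{st.value.lower()}_errors"], f"{st} errors", rownum)
                if v is not None:
                    errors[st] = v
            mmse = _cell_int(raw["mmse"], "mmse", rownum)
            kwargs: dict = {}
            if schema == "longitudinal":
                kwargs["interval_years"] = _cell_float(
                    raw["interval_years"], "interval_years", rownum
                )
                fu = {}
                for st in Subtest:
                    v = _cell_int(
                        raw[f"{st.value.lower()}_time_fu"], f"{st} follow-up time", rownum
                    )
                    if v is not None:
                        fu[st] = v
                kwargs["times_followup"] = fu
            records.append(
                ParticipantRecord(
                    id=str(raw["id"]),
                    age=age,
                    education=edu,
                    sex=Sex.parse(raw["sex"]),
                    times=times,
                    errors=errors,
                    mmse=mmse,
                    **kwargs,
                )
            )
        except (CohortValidationError, ValueError) as exc:
            problems.append(f"row {rownum}: {exc}" if "row" not in str(exc) else str(exc))
    if problems:
        raise CohortValidationError("; ".join(problems))
    logger.info("read %d records from %s (%s schema)", len(records), path, schema)
    return CohortTable(records=records, provenance=provenance or str(path))


def write_cohort(
    cohort: CohortTable, path: str | Path, schema: str = "cross_sectional"
) -> Path:
    """Serialize a cohort; ``read_cohort`` of the result round-trips exactly."""
    path = Path(path)
    frame = cohort.to_frame(schema)
    # integer-valued float columns are written without a trailing ".0"
    out = frame.copy()
    for col in out.columns:
        if col in ("id", "sex", "age", "interval_years"):
            continue
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else str(int(v)) if float(v).is_integer() else str(v)
        )
    out.to_csv(path, index=False, na_rep="")
    logger.info("wrote %d records to %s", len(cohort), path)
    return path


@dataclass
class RunConfig:
    """Pipeline configuration; file values are overridden by CLI flags.

    alpha_selection is the nested-F criterion used during model
    simplification; alpha_eval the conventional level used when auditing
    external norms; cutoff_t the low-score threshold (1.5 SD below the
    normative mean).
    """

    seed: int = 0
    alpha_selection: float = 0.01
    alpha_eval: float = 0.05
    cutoff_t: float = 35.0
    retest_max_interval: float = 5.0
    subtests: tuple[Subtest, ...] = tuple(Subtest)

    def __post_init__(self) -> None:
        for name in ("alpha_selection", "alpha_eval"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if not (0.0 < self.cutoff_t < 100.0):
            raise ValueError(f"cutoff_t must be in (0, 100), got {self.cutoff_t}")
        if self.retest_max_interval <= 0:
            raise ValueError("retest_max_interval must be positive")
        self.subtests = tuple(
            st if isinstance(st, Subtest) else Subtest(st) for st in self.subtests
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: object) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        payload = dataclasses.asdict(self)
        payload["subtests"] = [st.value for st in self.subtests]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
        return Path(path)
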