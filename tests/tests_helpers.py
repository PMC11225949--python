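"""Small construction helpers shared across test modules."""

import numpy as np

from cwitnorms import CohortTable, ParticipantRecord, Sex, Subtest


def cohort_from_arrays(ages, edus, females, times=None, intervals=None, times_fu=None):
    """Build a cohort from parallel arrays.

    ``times``/``times_fu`` map a subtest to an integer array; ``intervals``
    adds retest intervals (longitudinal schema).
    """
    n = len(ages)
    records = []
    for i in range(n):
        t = {st: int(arr[i]) for st, arr in (times or {}).items()}
        fu = {st: int(arr[i]) for st, arr in (times_fu or {}).items()}
        records.append(
            ParticipantRecord(
                id=f"Q{i:05d}",
                age=float(ages[i]),
                education=int(edus[i]),
                sex=Sex.FEMALE if females[i] else Sex.MALE,
                times=t,
                times_followup=fu,
                interval_years=None if intervals is None else float(intervals[i]),
            )
        )
    return CohortTable(records=records)
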