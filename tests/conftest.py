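import numpy as np
import pytest

from cwitnorms import (
    CohortTable,
    ParticipantRecord,
    Sex,
    Subtest,
    norwegian_norms,
)


@pytest.fixture(scope="session")
def norms():
    return norwegian_norms()


@pytest.fixture()
def two_record_cohort():
    """Tiny cohort exercising missingness: P2 lacks errors and CWIT-2."""
    return CohortTable(
        records=[
            ParticipantRecord(
                id="P1",
                age=70.0,
                education=17,
                sex=Sex.MALE,
                times={Subtest.CWIT1: 35, Subtest.CWIT2: 22, Subtest.CWIT3: 55,
                       Subtest.CWIT4: 62},
                errors={Subtest.CWIT3: 1, Subtest.CWIT4: 0},
                mmse=29,
            ),
            ParticipantRecord(
                id="P2",
                age=55.0,
                education=12,
                sex=Sex.FEMALE,
                times={Subtest.CWIT1: 28, Subtest.CWIT3: 78, Subtest.CWIT4: 85},
            ),
        ],
        provenance="fixture",
    )


def make_cohort(ages, edus, females, times=None, ids=None):
    """Build a cohort from parallel arrays (times: {subtest: array})."""
    n = len(ages)
    ids = ids or [f"Q{i}" for i in range(n)]
    records = []
    for i in range(n):
        t = {}
        if times:
            for st, arr in times.items():
                t[st] = int(arr[i])
        records.append(
            ParticipantRecord(
                id=ids[i],
                age=float(ages[i]),
                education=int(edus[i]),
                sex=Sex.FEMALE if females[i] else Sex.MALE,
                times=t,
            )
        )
    return CohortTable(records=records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
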