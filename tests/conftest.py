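from __future__ import annotations

import math

import pytest

from faerspv.cohort_builder import Cohort
from faerspv.faers_io import CaseReport, DrugEntry


def make_case(
    primaryid: str = "11",
    caseid: str | None = None,
    caseversion: int = 1,
    age_years: float | None = 15.0,
    sex: str = "male",
    drugs: list[str] = ("RISPERIDONE",),
    reactions: list[str] = ("Headache",),
    indications: list[str] = (),
    receipt_date=None,
) -> CaseReport:
    return CaseReport(
        primaryid=primaryid,
        caseid=caseid if caseid is not None else primaryid[:-1] or primaryid,
        caseversion=caseversion,
        receipt_date=receipt_date,
        age_years=age_years,
        sex=sex,
        drugs=[
            DrugEntry(verbatim_name=d, normalized_name=d, role="primary_suspect")
            for d in drugs
        ],
        reactions=list(reactions),
        indications=list(indications),
    )


def cohort_from_cells(
    drug: str, case_event: str, control_event: str, a: int, b: int, c: int, d: int
) -> Cohort:
    """Build a cohort realizing exact 2x2 cell counts — an enumeration
    scaffold for disproportionality tests."""
    cases = []
    spec = [
        (a, [drug], [case_event]),
        (b, [drug], [control_event]),
        (c, ["OTHER DRUG"], [case_event]),
        (d, ["OTHER DRUG"], [control_event]),
    ]
    i = 0
    for count, drugs, reactions in spec:
        for _ in range(count):
            i += 1
            cases.append(make_case(primaryid=f"{i}1", caseid=str(i), drugs=drugs, reactions=reactions))
    return Cohort(cases=cases)


@pytest.fixture
def ln8() -> float:
    return math.log(8.0)
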