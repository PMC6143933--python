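"""Age normalization, adolescent cohort filtering and sex breakdowns."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ._util import round_half_up
from .faers_io import CaseReport

#: Multiplicative factor from one unit to years (value_in_years = value * factor).
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: FAERS age-group code for adolescents (used only by the opt-in
#: missing-age admission rule).
ADOLESCENT_AGE_GROUP_CODE = "A"


def normalize_age(age_value: str | float | int | None, age_code: str | None) -> float | None:
    """Convert a raw FAERS (age, age_cod) pair to years.

    Unknown unit codes, unparseable or negative values yield ``None``
    (missing is a value here, not an error).
    """
    if age_value is None or age_code is None:
        return None
    factor = AGE_UNIT_TO_YEARS.get(str(age_code).strip().upper())
    if factor is None:
        return None
    try:
        value = float(str(age_value).strip())
    except ValueError:
        return None
    if not math.isfinite(value) or value < 0:
        return None
    return value * factor


@dataclass
class SexBreakdown:
    n_total: int
    n_male: int
    n_female: int
    n_undefined: int
    pct_male: float | None
    pct_female: float | None
    pct_undefined: float | None

    @classmethod
    def from_counts(cls, n_male: int, n_female: int, n_undefined: int) -> "SexBreakdown":
        total = n_male + n_female + n_undefined
        if total == 0:
            return cls(0, 0, 0, 0, None, None, None)
        return cls(
            n_total=total,
            n_male=n_male,
            n_female=n_female,
            n_undefined=n_undefined,
            pct_male=round_half_up(100.0 * n_male / total, 1),
            pct_female=round_half_up(100.0 * n_female / total, 1),
            pct_undefined=round_half_up(100.0 * n_undefined / total, 1),
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def sex_breakdown(cases: Sequence[CaseReport]) -> SexBreakdown:
    """Count cases by sex; blank/unknown codes count as undefined."""
    male = sum(1 for c in cases if c.sex == "male")
    female = sum(1 for c in cases if c.sex == "female")
    undefined = len(cases) - male - female
    return SexBreakdown.from_counts(male, female, undefined)


@dataclass
class Cohort:
    """A filtered set of case reports with filter provenance."""

    cases: list[CaseReport]
    filters: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def summary(self) -> dict:
        sb = sex_breakdown(self.cases)
        return {"n_cases": self.n_cases, "sex": sb.to_dict(), "filters": self.filters}

    def summary_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.summary(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def filter_adolescent(
    cases: Sequence[CaseReport],
    min_years: float = 12.0,
    max_years_exclusive: float = 18.0,
    admit_age_group_code: bool = False,
) -> Cohort:
    """Retain cases with ``min_years <= age_years < max_years_exclusive``.

    Cases with missing normalized age are excluded, unless
    ``admit_age_group_code`` is set and the report's FAERS age-group code
    marks it adolescent.
    """
    if min_years >= max_years_exclusive:
        raise ValueError(f"min_years ({min_years}) must be < max_years_exclusive ({max_years_exclusive})")
    kept = []
    for case in cases:
        if case.age_years is None:
            if admit_age_group_code and case.age_group.strip().upper() == ADOLESCENT_AGE_GROUP_CODE:
                kept.append(case)
            continue
        if min_years <= case.age_years < max_years_exclusive:
            kept.append(case)
    return Cohort(
        cases=kept,
        filters={
            "age_min_years": min_years,
            "age_max_years_exclusive": max_years_exclusive,
            "missing_age_admitted_by_group_code": admit_age_group_code,
            "n_input_cases": len(cases),
        },
    )
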