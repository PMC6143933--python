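"""Designated-control-event disproportionality statistics.

The case/non-case design here fixes a single control preferred term (the
most-reported ADR in the cohort) and, for each case PT of interest, builds
2x2 tables of drug exposure against (case event vs control event).  Reports
mentioning *both* events have no defined outcome in this design and are
excluded (and counted).  The reporting odds ratio is the cross-ratio
``(a/b)/(c/d)`` and is computed two ways:

- closed form with a Wald interval on the log scale, and
- a one-predictor binomial logistic regression on the eligible reports,
  whose exponentiated slope is the identical quantity (the 2x2 logistic
  model is saturated) — the two routes cross-check each other.

PRR and RRR follow their conventional all-report definitions.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort_builder import Cohort
from .faers_io import CaseReport, normalize_drug_name

logger = logging.getLogger(__name__)

Z_95 = 1.96  # fixed 95% level

SUSPECT_ROLES = frozenset(["primary_suspect", "secondary_suspect"])
ALL_ROLES = frozenset(["primary_suspect", "secondary_suspect", "concomitant", "interacting"])


@dataclass
class ContingencyTable:
    """2x2 counts of drug exposure x (case event vs control event).

    a: drug & case event;  b: drug & control event;
    c: no drug & case event;  d: no drug & control event.
    ``corrected`` is True iff any raw cell is zero (Haldane–Anscombe +0.5
    applied downstream).
    """

    drug: str
    case_event: str
    control_event: str
    a: int
    b: int
    c: int
    d: int
    n_both_excluded: int = 0

    @property
    def corrected(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def cells(self) -> tuple[float, float, float, float]:
        """Cell values used for estimation: +0.5 on all four if any is zero."""
        if self.corrected:
            return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5
        return float(self.a), float(self.b), float(self.c), float(self.d)

    @property
    def n_eligible(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class DisproportionalityResult:
    drug: str
    case_event: str
    control_event: str
    statistic: str  # ROR | PRR | RRR
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # closed_form | logistic
    corrected: bool = False
    unstable: bool = False
    table: ContingencyTable | None = None
    closed_form: "DisproportionalityResult | None" = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _safe_exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


def wald_interval(log_estimate: float, se: float) -> tuple[float, float]:
    return _safe_exp(log_estimate - Z_95 * se), _safe_exp(log_estimate + Z_95 * se)


def wald_p_value(log_estimate: float, se: float) -> float:
    if se == 0:
        return 1.0 if log_estimate == 0 else 0.0
    return 2.0 * stats.norm.sf(abs(log_estimate) / se)


def wald_point_estimate(ci_low: float, ci_high: float) -> float:
    """Point estimate implied by a log-symmetric (Wald) 95% interval: the
    geometric mean of the bounds."""
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("Wald interval bounds must be positive")
    return math.sqrt(ci_low * ci_high)


def _case_mentions(case: CaseReport, pt: str) -> bool:
    return pt.casefold() in case.reaction_set


def _case_exposed(case: CaseReport, drug_norm: str, roles: frozenset[str]) -> bool:
    if roles is ALL_ROLES:
        return drug_norm in case.drug_names
    return any(d.normalized_name == drug_norm and d.role in roles for d in case.drugs)


def _eligible_split(
    cohort: Cohort, case_event: str, control_event: str
) -> tuple[list[tuple[CaseReport, bool]], int]:
    """Partition the cohort into eligible reports (mentioning exactly one of
    the two PTs, tagged True for the case event) and a both-event count."""
    if case_event.casefold() == control_event.casefold():
        raise ValueError("case_event and control_event must differ")
    case_pt = case_event.casefold()
    control_pt = control_event.casefold()
    eligible: list[tuple[CaseReport, bool]] = []
    both = 0
    for case in cohort.cases:
        pts = case.reaction_set
        has_case = case_pt in pts
        has_control = control_pt in pts
        if has_case and has_control:
            both += 1
        elif has_case or has_control:
            eligible.append((case, has_case))
    return eligible, both


def _fill_cells(
    eligible: list[tuple[CaseReport, bool]], drug_norm: str, roles: frozenset[str]
) -> tuple[int, int, int, int]:
    a = b = c = d = 0
    for case, has_case in eligible:
        exposed = _case_exposed(case, drug_norm, roles)
        if has_case:
            a += exposed
            c += not exposed
        else:
            b += exposed
            d += not exposed
    return a, b, c, d


def build_contingency(
    cohort: Cohort,
    drug: str,
    case_event: str,
    control_event: str,
    roles: frozenset[str] = ALL_ROLES,
) -> ContingencyTable:
    """Build the designated-control 2x2 table.

    Eligible reports mention exactly one of the two PTs (XOR); matching is
    case-insensitive exact.  Raises if no report is eligible.
    """
    eligible, both = _eligible_split(cohort, case_event, control_event)
    drug_norm = normalize_drug_name(drug)
    a, b, c, d = _fill_cells(eligible, drug_norm, roles)
    if a + b + c + d == 0:
        raise ValueError(
            f"no eligible reports mention exactly one of {case_event!r} / {control_event!r}"
        )
    return ContingencyTable(
        drug=drug_norm, case_event=case_event, control_event=control_event,
        a=a, b=b, c=c, d=d, n_both_excluded=both,
    )


def ror_closed_form(t: ContingencyTable) -> DisproportionalityResult:
    """Cross-ratio ROR with Wald CI and two-sided normal p-value."""
    a, b, c, d = t.cells()
    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_est = math.log(estimate)
    lo, hi = wald_interval(log_est, se)
    return DisproportionalityResult(
        drug=t.drug, case_event=t.case_event, control_event=t.control_event,
        statistic="ROR", estimate=estimate, ci_low=lo, ci_high=hi,
        p_value=wald_p_value(log_est, se), method="closed_form",
        corrected=t.corrected, table=t,
    )


def ror_logistic_from_table(t: ContingencyTable, tol: float = 1e-10) -> DisproportionalityResult:
    """Fit outcome(case=1/control=0) ~ exposure by IRLS on the aggregated
    2x2 and exponentiate the slope.

    A zero cell means (quasi-)separation or an undefined margin: the result
    is flagged unstable and carries the Haldane-corrected closed form in
    ``closed_form``.
    """
    unstable = t.corrected
    closed = ror_closed_form(t)
    if unstable:
        # a zero cell separates the 2x2 likelihood: the MLE diverges, so
        # report the Haldane-corrected closed form under the unstable flag
        return DisproportionalityResult(
            drug=t.drug, case_event=t.case_event, control_event=t.control_event,
            statistic="ROR", estimate=closed.estimate, ci_low=closed.ci_low,
            ci_high=closed.ci_high, p_value=closed.p_value, method="logistic",
            corrected=True, unstable=True, table=t, closed_form=closed,
        )
    # aggregated binomial rows: exposed and unexposed
    endog = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    exog = np.array([[1.0, 1.0], [1.0, 0.0]])
    try:
        model = sm.GLM(endog, exog, family=sm.families.Binomial())
        with warnings.catch_warnings():
            # the aggregated 2x2 model is saturated (df_resid = 0); the
            # scale estimate and perfect-prediction checks warn spuriously
            warnings.simplefilter("ignore")
            fit = model.fit(tol=tol, maxiter=200)
        if not fit.converged:
            unstable = True
        coef = float(fit.params[1])
        se = float(fit.bse[1])
        estimate = math.exp(coef)
        lo, hi = wald_interval(coef, se)
        p = wald_p_value(coef, se)
    except (ValueError, np.linalg.LinAlgError, ZeroDivisionError):
        unstable = True
        estimate, lo, hi, p = closed.estimate, closed.ci_low, closed.ci_high, closed.p_value
    return DisproportionalityResult(
        drug=t.drug, case_event=t.case_event, control_event=t.control_event,
        statistic="ROR", estimate=estimate, ci_low=lo, ci_high=hi, p_value=p,
        method="logistic", corrected=t.corrected, unstable=unstable,
        table=t, closed_form=closed,
    )


def ror_logistic(
    cohort: Cohort,
    drug: str,
    case_event: str,
    control_event: str,
    roles: frozenset[str] = ALL_ROLES,
) -> DisproportionalityResult:
    t = build_contingency(cohort, drug, case_event, control_event, roles=roles)
    return ror_logistic_from_table(t)


def _exposure_event_counts(
    cohort: Cohort, drug: str, event: str, roles: frozenset[str]
) -> tuple[int, int, int, int]:
    """Counts over ALL cohort reports: (drug&event, drug&~event,
    ~drug&event, ~drug&~event)."""
    drug_norm = normalize_drug_name(drug)
    a = b = c = d = 0
    for case in cohort.cases:
        exposed = _case_exposed(case, drug_norm, roles)
        has_event = _case_mentions(case, event)
        if exposed:
            a += has_event
            b += not has_event
        else:
            c += has_event
            d += not has_event
    return a, b, c, d


def build_exposure_event_table(
    cohort: Cohort, drug: str, event: str, roles: frozenset[str] = ALL_ROLES
) -> ContingencyTable:
    """2x2 of drug exposure x (event vs any other outcome), over all
    reports — the table underlying PRR/RRR and the conventional
    all-other-reports ROR."""
    a, b, c, d = _exposure_event_counts(cohort, drug, event, roles)
    return ContingencyTable(
        drug=normalize_drug_name(drug), case_event=event, control_event="<all other reports>",
        a=a, b=b, c=c, d=d,
    )


def prr(
    cohort: Cohort, drug: str, event: str, roles: frozenset[str] = ALL_ROLES
) -> DisproportionalityResult:
    """Proportional reporting ratio over all cohort reports."""
    a, b, c, d = _exposure_event_counts(cohort, drug, event, roles)
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError(f"drug {drug!r} must occur in both exposure strata of the cohort")
    corrected = a == 0 or c == 0
    af, bf, cf, df = (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    estimate = (af / (af + bf)) / (cf / (cf + df))
    se = math.sqrt(1 / af - 1 / (af + bf) + 1 / cf - 1 / (cf + df))
    log_est = math.log(estimate)
    lo, hi = wald_interval(log_est, se)
    return DisproportionalityResult(
        drug=normalize_drug_name(drug), case_event=event, control_event="<all other reports>",
        statistic="PRR", estimate=estimate, ci_low=lo, ci_high=hi,
        p_value=wald_p_value(log_est, se), method="closed_form", corrected=corrected,
    )


def rrr(
    cohort: Cohort, drug: str, event: str, roles: frozenset[str] = ALL_ROLES
) -> DisproportionalityResult:
    """Relative reporting ratio: observed / expected under independence,
    with a Poisson-based interval SE(log RRR) = sqrt(1/a)."""
    a, b, c, d = _exposure_event_counts(cohort, drug, event, roles)
    n_total = a + b + c + d
    n_drug = a + b
    n_event = a + c
    if n_drug == 0 or n_event == 0:
        raise ValueError(f"drug {drug!r} and event {event!r} must both occur in the cohort")
    corrected = a == 0
    af = a + 0.5 if corrected else float(a)
    estimate = (af * n_total) / (n_drug * n_event)
    se = math.sqrt(1 / af)
    log_est = math.log(estimate)
    lo, hi = wald_interval(log_est, se)
    return DisproportionalityResult(
        drug=normalize_drug_name(drug), case_event=event, control_event="<all other reports>",
        statistic="RRR", estimate=estimate, ci_low=lo, ci_high=hi,
        p_value=wald_p_value(log_est, se), method="closed_form", corrected=corrected,
    )


def scan_drugs(
    cohort: Cohort,
    case_event: str,
    control_event: str,
    drugs: Sequence[str],
    roles: frozenset[str] = ALL_ROLES,
) -> list[DisproportionalityResult]:
    """One logistic ROR per drug against the designated control, sorted by
    estimate descending (estimates < 1 mean association with the control
    event).  Drugs absent from the eligible reports are skipped with a log
    entry."""
    if not drugs:
        raise ValueError("drugs list must be non-empty")
    eligible, both = _eligible_split(cohort, case_event, control_event)
    if not eligible:
        raise ValueError(
            f"no eligible reports mention exactly one of {case_event!r} / {control_event!r}"
        )
    results = []
    for drug in drugs:
        drug_norm = normalize_drug_name(drug)
        a, b, c, d = _fill_cells(eligible, drug_norm, roles)
        t = ContingencyTable(
            drug=drug_norm, case_event=case_event, control_event=control_event,
            a=a, b=b, c=c, d=d, n_both_excluded=both,
        )
        if t.a + t.b == 0:
            logger.warning(
                "scan: drug %s absent from reports eligible for %s vs %s — skipped",
                drug, case_event, control_event,
            )
            continue
        results.append(ror_logistic_from_table(t))
    results.sort(key=lambda r: (-r.estimate, r.drug))
    return results


def write_scan_csv(results: Sequence[DisproportionalityResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["drug", "case_event", "control_event", "statistic", "estimate",
             "ci_low", "ci_high", "p_value", "corrected", "unstable"]
        )
        for r in results:
            writer.writerow(
                [r.drug, r.case_event, r.control_event, r.statistic,
                 f"{r.estimate:.6g}", f"{r.ci_low:.6g}", f"{r.ci_high:.6g}",
                 f"{r.p_value:.3g}", r.corrected, r.unstable]
            )
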