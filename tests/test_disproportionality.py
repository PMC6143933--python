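import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.disproportionality import (
    ContingencyTable,
    build_contingency,
    build_exposure_event_table,
    prr,
    ror_closed_form,
    ror_logistic,
    ror_logistic_from_table,
    rrr,
    scan_drugs,
    wald_point_estimate,
)
from faerspv.cohort_builder import Cohort
from faerspv.synthetic_faers import SyntheticConfig, sample_cohort

from conftest import cohort_from_cells, make_case


def _table(a, b, c, d, drug="D", case="CaseEvent", control="ControlEvent"):
    return ContingencyTable(drug=drug, case_event=case, control_event=control,
                            a=a, b=b, c=c, d=d)


class TestBuildContingency:
    def test_one_case_per_cell(self):
        cohort = cohort_from_cells("D", "CaseEvent", "ControlEvent", 1, 1, 1, 1)
        t = build_contingency(cohort, "D", "CaseEvent", "ControlEvent")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_both_event_case_excluded_and_counted(self):
        cohort = cohort_from_cells("D", "CaseEvent", "ControlEvent", 1, 1, 1, 1)
        cohort.cases.append(
            make_case(primaryid="991", caseid="99", drugs=["D"],
                      reactions=["CaseEvent", "ControlEvent"])
        )
        t = build_contingency(cohort, "D", "CaseEvent", "ControlEvent")
        assert t.n_both_excluded == 1
        assert t.n_eligible == 4

    def test_pt_matching_case_insensitive(self):
        cohort = cohort_from_cells("D", "Hyperglycaemia", "Diarrhoea", 2, 1, 1, 1)
        t = build_contingency(cohort, "D", "HYPERGLYCAEMIA", "diarrhoea")
        assert t.a == 2

    def test_same_pt_rejected(self):
        cohort = cohort_from_cells("D", "A", "B", 1, 1, 1, 1)
        with pytest.raises(ValueError):
            build_contingency(cohort, "D", "A", "a")

    def test_no_eligible_reports_errors_with_both_pts(self):
        cohort = Cohort(cases=[make_case(reactions=["Unrelated"])])
        with pytest.raises(ValueError, match="Pneumothorax.*Diarrhoea"):
            build_contingency(cohort, "D", "Pneumothorax", "Diarrhoea")

    def test_cells_match_brute_force_enumeration(self):
        # independent oracle: re-count every cell by direct enumeration
        cfg = SyntheticConfig(n_cases=600, seed=23,
                              signal_matrix={("RISPERIDONE", "Hyperglycaemia"): 1.0})
        cohort = sample_cohort(cfg)
        t = build_contingency(cohort, "RISPERIDONE", "Hyperglycaemia", "Diarrhoea")
        a = b = c = d = both = 0
        for case in cohort.cases:
            pts = {r.lower() for r in case.reactions}
            has_case, has_control = "hyperglycaemia" in pts, "diarrhoea" in pts
            exposed = "RISPERIDONE" in {x.normalized_name for x in case.drugs}
            if has_case and has_control:
                both += 1
            elif has_case:
                a, c = a + exposed, c + (not exposed)
            elif has_control:
                b, d = b + exposed, d + (not exposed)
        assert (t.a, t.b, t.c, t.d, t.n_both_excluded) == (a, b, c, d, both)


class TestRorClosedForm:
    def test_symmetric_table(self):
        r = ror_closed_form(_table(10, 10, 10, 10))
        assert r.estimate == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_hand_worked_example(self):
        # (20*40)/(5*10) = 16; SE = sqrt(1/20+1/5+1/10+1/40) = sqrt(0.375)
        r = ror_closed_form(_table(20, 5, 10, 40))
        assert r.estimate == pytest.approx(16.0)
        assert r.ci_low == pytest.approx(4.8179, abs=1e-3)
        assert r.ci_high == pytest.approx(53.135, abs=1e-2)

    def test_haldane_correction(self):
        r = ror_closed_form(_table(0, 5, 10, 40))
        assert r.corrected
        assert r.estimate == pytest.approx((0.5 * 40.5) / (5.5 * 10.5))

    @given(st.tuples(*[st.integers(1, 300)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_wald_symmetry(self, cells):
        r = ror_closed_form(_table(*cells))
        assert r.estimate == pytest.approx(wald_point_estimate(r.ci_low, r.ci_high), rel=1e-9)

    @given(st.tuples(*[st.integers(1, 300)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_relabeling_inverts_estimate(self, cells):
        a, b, c, d = cells
        fwd = ror_closed_form(_table(a, b, c, d))
        rev = ror_closed_form(_table(b, a, d, c))  # case <-> control swap
        assert rev.estimate == pytest.approx(1.0 / fwd.estimate, rel=1e-12)
        assert rev.ci_low == pytest.approx(1.0 / fwd.ci_high, rel=1e-12)
        assert rev.ci_high == pytest.approx(1.0 / fwd.ci_low, rel=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-9)


class TestRorLogistic:
    def test_symmetric_table(self):
        r = ror_logistic_from_table(_table(10, 10, 10, 10))
        assert r.estimate == pytest.approx(1.0, abs=1e-8)
        assert r.method == "logistic"

    def test_matches_closed_form_on_positive_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            t = _table(int(a), int(b), int(c), int(d))
            logi = ror_logistic_from_table(t)
            closed = ror_closed_form(t)
            assert logi.estimate == pytest.approx(closed.estimate, rel=1e-6)
            assert logi.ci_low == pytest.approx(closed.ci_low, rel=1e-4)
            assert logi.p_value == pytest.approx(closed.p_value, rel=1e-3, abs=1e-12)

    def test_zero_cell_flagged_unstable_with_fallback(self):
        r = ror_logistic_from_table(_table(0, 5, 10, 40))
        assert r.unstable
        assert r.closed_form is not None
        assert r.closed_form.corrected

    def test_cohort_wrapper(self):
        cohort = cohort_from_cells("D", "A", "B", 20, 5, 10, 40)
        r = ror_logistic(cohort, "D", "A", "B")
        assert r.estimate == pytest.approx(16.0, rel=1e-6)


class TestPrr:
    def test_nine_fold_example(self):
        # drug: 100 reports, 10 events; non-drug: 900 reports, 10 events
        cases = []
        layout = [(10, ["D"], ["E"]), (90, ["D"], ["Other"]),
                (10, ["X"], ["E"]), (890, ["X"], ["Other"])]
        i = 0
        for count, drugs, reactions in layout:
            for _ in range(count):
                i += 1
                cases.append(make_case(primaryid=f"{i}1", caseid=str(i),
                                       drugs=drugs, reactions=reactions))
        r = prr(Cohort(cases=cases), "D", "E")
        assert r.estimate == pytest.approx(9.0)
        assert r.statistic == "PRR"

    def test_identical_rates_give_unity(self):
        cases = []
        layout = [(5, ["D"], ["E"]), (45, ["D"], ["Other"]),
                (5, ["X"], ["E"]), (45, ["X"], ["Other"])]
        i = 0
        for count, drugs, reactions in layout:
            for _ in range(count):
                i += 1
                cases.append(make_case(primaryid=f"{i}1", caseid=str(i),
                                       drugs=drugs, reactions=reactions))
        assert prr(Cohort(cases=cases), "D", "E").estimate == pytest.approx(1.0)

    def test_zero_cell_corrected(self):
        cases = [make_case(primaryid="11", caseid="1", drugs=["D"], reactions=["Other"]),
                 make_case(primaryid="21", caseid="2", drugs=["X"], reactions=["E"])]
        r = prr(Cohort(cases=cases), "D", "E")
        assert r.corrected


class TestRrr:
    def test_worked_example(self):
        # a=10, N=1000, n_drug=100, n_event=20 -> RRR = 5
        cases = []
        layout = [(10, ["D"], ["E"]), (90, ["D"], ["Other"]),
                (10, ["X"], ["E"]), (890, ["X"], ["Other"])]
        i = 0
        for count, drugs, reactions in layout:
            for _ in range(count):
                i += 1
                cases.append(make_case(primaryid=f"{i}1", caseid=str(i),
                                       drugs=drugs, reactions=reactions))
        r = rrr(Cohort(cases=cases), "D", "E")
        assert r.estimate == pytest.approx(5.0)
        assert r.ci_low == pytest.approx(math.exp(math.log(5) - 1.96 * math.sqrt(0.1)))

    def test_independence_gives_unity(self):
        cases = []
        layout = [(2, ["D"], ["E"]), (8, ["D"], ["Other"]),
                (18, ["X"], ["E"]), (72, ["X"], ["Other"])]
        i = 0
        for count, drugs, reactions in layout:
            for _ in range(count):
                i += 1
                cases.append(make_case(primaryid=f"{i}1", caseid=str(i),
                                       drugs=drugs, reactions=reactions))
        assert rrr(Cohort(cases=cases), "D", "E").estimate == pytest.approx(1.0)

    def test_null_monte_carlo_mean_near_unity(self):
        # under independence the mean log-RRR over replicates sits within
        # 2 SE of 0
        cfg_base = dict(
            drug_catalog=(("D", 0.3),),
            event_catalog=(("E", 0.1), ("Diarrhoea", 0.2)),
        )
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(300):
            cfg = SyntheticConfig(n_cases=600, **cfg_base)
            cohort = sample_cohort(cfg, rng=rng)
            estimates.append(rrr(cohort, "D", "E").estimate)
        mean = np.mean(estimates)
        sem = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(mean - 1.0) < 2 * sem + 0.02  # small-sample ratio-bias allowance


class TestScanDrugs:
    def test_antisymmetric_pair_ordering(self):
        cases = []
        i = 0
        layout = [
            (20, ["D1"], ["CaseEvent"]), (5, ["D1"], ["ControlEvent"]),
            (5, ["D2"], ["CaseEvent"]), (20, ["D2"], ["ControlEvent"]),
            (10, ["D3"], ["CaseEvent"]), (40, ["D3"], ["ControlEvent"]),
        ]
        for count, drugs, reactions in layout:
            for _ in range(count):
                i += 1
                cases.append(make_case(primaryid=f"{i}1", caseid=str(i),
                                       drugs=drugs, reactions=reactions))
        results = scan_drugs(Cohort(cases=cases), "CaseEvent", "ControlEvent", ["D1", "D2"])
        assert [r.drug for r in results] == ["D1", "D2"]
        # oracle cell counts by enumeration: D1 (20,5 | 15,60), D2 (5,20 | 30,45)
        assert results[0].estimate == pytest.approx((20 * 60) / (5 * 15), rel=1e-6)
        assert results[1].estimate == pytest.approx((5 * 45) / (20 * 30), rel=1e-6)
        assert results[0].estimate > 1 > results[1].estimate

    def test_empty_drug_list_rejected(self):
        with pytest.raises(ValueError):
            scan_drugs(Cohort(cases=[make_case()]), "A", "B", [])

    def test_absent_drug_skipped(self):
        cohort = cohort_from_cells("D", "A", "B", 5, 5, 5, 5)
        results = scan_drugs(cohort, "A", "B", ["D", "NOT PRESENT ANYWHERE"])
        assert [r.drug for r in results] == ["D"]

    def test_injected_signal_ranks_first_seeded(self):
        nulls = tuple((f"NULL{i}", 0.2) for i in range(9))
        cfg = SyntheticConfig(
            n_cases=4000, seed=17,
            drug_catalog=(("SIGNAL", 0.25),) + nulls,
            event_catalog=(("CaseEvent", 0.2), ("ControlEvent", 0.25)),
            signal_matrix={("SIGNAL", "CaseEvent"): math.log(8)},
        )
        cohort = sample_cohort(cfg)
        drugs = [name for name, _ in cfg.drug_catalog]
        results = scan_drugs(cohort, "CaseEvent", "ControlEvent", drugs)
        assert results[0].drug == "SIGNAL"
        assert results[0].significant


class TestRareEventConcordance:
    def test_ror_prr_rrr_agree_at_low_prevalence(self):
        cfg = SyntheticConfig(
            n_cases=200_000, seed=31,
            drug_catalog=(("D", 0.01), ("FILLERISH", 0.9)),
            event_catalog=(("E", 0.004), ("Diarrhoea", 0.05)),
            signal_matrix={("D", "E"): math.log(3)},
        )
        cohort = sample_cohort(cfg)
        t = build_exposure_event_table(cohort, "D", "E")
        ror_est = ror_closed_form(t).estimate
        prr_est = prr(cohort, "D", "E").estimate
        rrr_est = rrr(cohort, "D", "E").estimate
        for x, y in [(ror_est, prr_est), (prr_est, rrr_est), (ror_est, rrr_est)]:
            assert abs(x - y) / y < 0.05


def test_wald_point_estimate_rejects_nonpositive():
    with pytest.raises(ValueError):
        wald_point_estimate(0.0, 2.0)
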