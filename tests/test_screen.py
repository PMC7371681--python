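"""Screen orchestration: plan enumeration, demography, tables, comparison."""

import math

import pytest

from prrscreen import (
    AEReport,
    AgeStratum,
    CLASS_ENTITY_NAME,
    Category,
    DrugEntity,
    PTDictionary,
    ReportSet,
    ScreenPlan,
    Sex,
    SignalResult,
    ValidationError,
    build_contingency,
    compare_across_entities,
    count_analyses,
    demography_table,
    results_from_frame,
    results_to_frame,
    run_screen,
    signal_table,
)

CAT = Category.OVARIAN_CYSTS_AND_NEOPLASMS


def mini_dict(*pts):
    return PTDictionary({p: CAT for p in pts})


def mini_entities():
    return (
        DrugEntity("class", frozenset({"d1", "d2"})),
        DrugEntity("d1", frozenset({"d1"})),
        DrugEntity("d2", frozenset({"d2"})),
    )


def mini_reports(n=40, seed_pts=("P", "Q")):
    reports = []
    ages = [10.0, 25.0, 50.0, 70.0, None]
    for i in range(n):
        drugs = {"d1"} if i % 4 == 0 else ({"d2"} if i % 4 == 1 else {"x"})
        pts = {seed_pts[0]} if i % 5 == 0 else set()
        reports.append(
            AEReport(f"r{i}", Sex.FEMALE, ages[i % 5], frozenset(drugs),
                     frozenset(pts))
        )
    return ReportSet(reports)


class TestCountAnalyses:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((383, 7, 4), (383, 2681, 12256, 15320)),
            ((1, 1, 1), (1, 1, 2, 4)),
            ((10, 3, 2), (10, 30, 80, 120)),
        ],
    )
    def test_breakdown(self, args, expected):
        c = count_analyses(*args)
        assert (c.class_overall, c.per_statin_overall, c.stratified,
                c.total) == expected

    @pytest.mark.parametrize("bad", [(0, 7, 4), (383, -1, 4), (383, 7, 0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValidationError):
            count_analyses(*bad)


class TestRunScreen:
    def test_one_result_per_planned_triple(self):
        rs = mini_reports()
        plan = ScreenPlan(entities=mini_entities(), pt_dict=mini_dict("P", "Q"))
        results = run_screen(rs, plan)
        expected = count_analyses(2, len(mini_entities()) - 1, 4).total
        assert len(results) == len(plan.entities) * 2 * 5 == expected
        triples = {(r.entity, r.pt, r.stratum) for r in results}
        assert len(triples) == len(results)  # each triple exactly once

    def test_single_triple_plan(self):
        rs = mini_reports()
        plan = ScreenPlan(
            entities=(DrugEntity("d1", frozenset({"d1"})),),
            pt_dict=mini_dict("P"),
            strata=(AgeStratum.OVERALL,),
        )
        results = run_screen(rs, plan)
        assert len(results) == 1

    def test_empty_reportset_rejected(self):
        plan = ScreenPlan(entities=mini_entities(), pt_dict=mini_dict("P"))
        with pytest.raises(ValidationError):
            run_screen(ReportSet([]), plan)

    def test_matches_scalar_contingency_path(self):
        rs = mini_reports()
        plan = ScreenPlan(entities=mini_entities(), pt_dict=mini_dict("P", "Q"))
        for res in run_screen(rs, plan):
            entity = next(e for e in plan.entities if e.name == res.entity)
            try:
                t = build_contingency(rs, entity, res.pt, res.stratum)
            except Exception:
                assert res.degenerate
                continue
            assert res.n == t.a

    def test_results_carry_category(self):
        rs = mini_reports()
        plan = ScreenPlan(entities=mini_entities(), pt_dict=mini_dict("P"))
        assert all(r.category is CAT for r in run_screen(rs, plan))

    def test_conservation_overall_a_at_least_stratum_sum(self):
        rs = mini_reports(n=60)
        plan = ScreenPlan(entities=mini_entities(), pt_dict=mini_dict("P", "Q"))
        results = run_screen(rs, plan)
        by = {(r.entity, r.pt, r.stratum): r for r in results}
        for entity in plan.entities:
            for pt in ("P", "Q"):
                overall = by[(entity.name, pt, AgeStratum.OVERALL)].n
                parts = sum(
                    by[(entity.name, pt, s)].n
                    for s in (AgeStratum.S_0_18, AgeStratum.S_19_39,
                              AgeStratum.S_40_59, AgeStratum.S_60_PLUS)
                )
                assert overall >= parts

    def test_conservation_equality_without_unknown_ages(self):
        reports = [
            AEReport(f"r{i}", Sex.FEMALE, float(20 + i), frozenset({"d1"}),
                     frozenset({"P"}))
            for i in range(10)
        ]
        rs = ReportSet(reports)
        plan = ScreenPlan(
            entities=(DrugEntity("d1", frozenset({"d1"})),),
            pt_dict=mini_dict("P"),
        )
        by = {r.stratum: r for r in run_screen(rs, plan)}
        parts = sum(
            by[s].n for s in (AgeStratum.S_0_18, AgeStratum.S_19_39,
                              AgeStratum.S_40_59, AgeStratum.S_60_PLUS)
        )
        assert by[AgeStratum.OVERALL].n == parts

    def test_deterministic_output(self):
        rs = mini_reports()
        plan = ScreenPlan(entities=mini_entities(), pt_dict=mini_dict("P", "Q"))
        a = results_to_frame(run_screen(rs, plan)).to_csv(index=False)
        b = results_to_frame(run_screen(rs, plan)).to_csv(index=False)
        assert a == b


class TestDemography:
    def test_percentage_arithmetic(self):
        reports = [
            AEReport("a", Sex.FEMALE, 10.0, frozenset({"d"}), frozenset())
        ] + [
            AEReport(f"b{i}", Sex.FEMALE, None, frozenset({"d"}), frozenset())
            for i in range(199)
        ]
        df = demography_table(ReportSet(reports),
                              [DrugEntity("d", frozenset({"d"}))])
        row = df.iloc[0]
        assert row["n_overall"] == 200
        assert row["n_0_18"] == 1
        assert row["pct_0_18"] == 0.50

    def test_zero_report_entity_yields_zero_row(self, caplog):
        rs = ReportSet(
            [AEReport("a", Sex.FEMALE, 40.0, frozenset({"x"}), frozenset())])
        with caplog.at_level("WARNING"):
            df = demography_table(rs, [DrugEntity("d", frozenset({"d"}))])
        assert df.iloc[0]["n_overall"] == 0
        assert any("zero reports" in m for m in caplog.messages)

    def test_percentages_exclude_unknown_age_from_bands(self):
        # 30% unknown ages: the four band percentages sum to ~70.
        reports = []
        for i in range(100):
            age = None if i < 30 else 50.0
            reports.append(
                AEReport(f"r{i}", Sex.FEMALE, age, frozenset({"d"}),
                         frozenset()))
        df = demography_table(ReportSet(reports),
                              [DrugEntity("d", frozenset({"d"}))])
        row = df.iloc[0]
        total_pct = (row["pct_0_18"] + row["pct_19_39"] + row["pct_40_59"]
                     + row["pct_60_plus"])
        assert total_pct == pytest.approx(70.0)


def _res(entity, pt, stratum, n, prr_v, chi2_v, flag, cat=CAT):
    return SignalResult(entity, pt, stratum, n, prr_v, chi2_v, flag, cat)


class TestSignalTable:
    def test_only_signalling_cells_populated(self):
        results = [
            _res("d1", "P", AgeStratum.OVERALL, 5, 3.0, 10.0, True),
            _res("d1", "P", AgeStratum.S_40_59, 2, 9.0, 8.0, False),
            _res("d1", "Q", AgeStratum.S_40_59, 1, 1.0, 0.1, False),
        ]
        df = signal_table(results, "d1")
        assert len(df) == 1
        row = df.iloc[0]
        assert row["pt"] == "P"
        assert row["prr_overall"] == "3.00"
        assert row["prr_40_59"] == "-"  # fails criteria, suppressed

    def test_entity_without_signals_gives_empty_table(self):
        results = [_res("d1", "P", AgeStratum.OVERALL, 1, 1.0, 0.0, False)]
        assert signal_table(results, "d1").empty

    def test_rows_ordered_by_category_then_descending_overall_prr(self):
        results = [
            _res("d1", "A", AgeStratum.OVERALL, 5, 3.0, 10.0, True,
                 Category.SEXUAL_FUNCTION_DISORDERS),
            _res("d1", "B", AgeStratum.OVERALL, 5, 9.0, 10.0, True, CAT),
            _res("d1", "C", AgeStratum.OVERALL, 5, 4.0, 10.0, True, CAT),
        ]
        df = signal_table(results, "d1")
        assert list(df["pt"]) == ["B", "C", "A"]


class TestComparison:
    def test_strongest_entity_marked(self):
        results = [
            _res("a", "P", AgeStratum.OVERALL, 5, 18.35, 100.0, True),
            _res("b", "P", AgeStratum.OVERALL, 5, 36.45, 200.0, True),
        ]
        df = compare_across_entities(results)
        assert len(df) == 1
        assert df.iloc[0]["strongest"] == "b"
        assert df.iloc[0]["a"] == "18.35"

    def test_single_statin_pt_excluded(self):
        results = [
            _res("a", "P", AgeStratum.OVERALL, 5, 18.35, 100.0, True),
            _res("b", "P", AgeStratum.OVERALL, 2, 3.0, 1.0, False),
        ]
        assert compare_across_entities(results).empty

    def test_class_entity_excluded_from_ranking(self):
        results = [
            _res(CLASS_ENTITY_NAME, "P", AgeStratum.OVERALL, 50, 99.0, 900.0,
                 True),
            _res("a", "P", AgeStratum.OVERALL, 5, 2.5, 10.0, True),
            _res("b", "P", AgeStratum.OVERALL, 5, 4.0, 10.0, True),
        ]
        df = compare_across_entities(results, class_entity=CLASS_ENTITY_NAME)
        assert df.iloc[0]["strongest"] == "b"
        assert CLASS_ENTITY_NAME not in df.columns

    def test_tie_marks_both_in_name_order(self):
        results = [
            _res("b", "P", AgeStratum.OVERALL, 5, 4.0, 10.0, True),
            _res("a", "P", AgeStratum.OVERALL, 5, 4.0, 10.0, True),
        ]
        df = compare_across_entities(results)
        assert df.iloc[0]["strongest"] == "a; b"


class TestResultsRoundTrip:
    def test_frame_round_trip_preserves_results(self):
        results = [
            _res("d1", "P", AgeStratum.OVERALL, 5, 3.0, 10.0, True),
            _res("d2", "Q", AgeStratum.S_60_PLUS, 0, math.inf, 5.0, False,
                 None),
        ]
        back = results_from_frame(results_to_frame(results))
        assert back == results
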