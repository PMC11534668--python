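"""ROR engine: oracle equivalence, invariants, Venn and cohort analyses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faerspv.meddra import AdeEvent
from faerspv.signals import (
    ContingencyTable,
    build_contingency,
    compute_ror,
    detect_signals,
    route_vs_route_ror,
    unique_pt_signals,
    venn_partition,
)


def oracle_ror(a, b, c, d):
    """Independent log-odds brute force: odds ratio as a product of exact
    integer ratios, CI assembled on the log scale term by term."""
    log_or = math.log(a) - math.log(c) - (math.log(b) - math.log(d))
    var = sum(1.0 / x for x in (a, b, c, d))
    half = 1.96 * math.sqrt(var)
    return (
        math.exp(log_or),
        math.exp(log_or - half),
        math.exp(log_or + half),
    )


class TestComputeRor:
    def test_worked_example_no_signal(self):
        r = compute_ror(ContingencyTable(20, 80, 10, 90), min_count=0)
        assert r.ror == pytest.approx(2.25)
        assert r.ci_low == pytest.approx(0.994, abs=5e-4)
        assert r.ci_high == pytest.approx(5.092, abs=5e-4)
        assert not r.is_signal

    def test_worked_example_signal(self):
        r = compute_ror(ContingencyTable(50, 950, 100, 8900), min_count=0)
        assert r.ror == pytest.approx(4.684, abs=5e-4)
        assert r.ci_low == pytest.approx(3.31, abs=5e-3)
        assert r.ci_high == pytest.approx(6.62, abs=5e-3)
        assert r.is_signal

    def test_balanced_table_is_exactly_null(self):
        r = compute_ror(ContingencyTable(10, 90, 10, 90), min_count=0)
        assert r.ror == 1.0
        assert not r.is_signal

    @pytest.mark.parametrize("table", [
        ContingencyTable(0, 100, 10, 90),
        ContingencyTable(10, 0, 10, 90),
        ContingencyTable(10, 90, 0, 100),
    ])
    def test_zero_cell_not_evaluable(self, table):
        r = compute_ror(table, min_count=0)
        assert not r.evaluable and not r.is_signal
        assert r.ror is None

    def test_min_count_gates_evaluability(self):
        table = ContingencyTable(2, 98, 10, 8990)
        assert not compute_ror(table, min_count=3).evaluable
        assert compute_ror(table, min_count=2).evaluable

    def test_continuity_correction_only_behind_flag(self):
        table = ContingencyTable(5, 95, 0, 100)
        assert not compute_ror(table, min_count=0).evaluable
        corrected = compute_ror(table, min_count=0, continuity_correction=True)
        assert corrected.evaluable
        assert corrected.ror == pytest.approx(
            oracle_ror(5.5, 95.5, 0.5, 100.5)[0]
        )

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 10, 10, 10)

    def test_exhaustive_small_grid_matches_oracle(self):
        # all tables with cells 1..12; the full 1..30 grid runs in the
        # acceptance suite
        grid = range(1, 13)
        for a in grid:
            for b in grid:
                for c in grid:
                    for d in grid:
                        r = compute_ror(ContingencyTable(a, b, c, d),
                                        min_count=0)
                        ror, lo, hi = oracle_ror(a, b, c, d)
                        assert math.isclose(r.ror, ror, rel_tol=1e-12)
                        assert math.isclose(r.ci_low, lo, rel_tol=1e-12)
                        assert math.isclose(r.ci_high, hi, rel_tol=1e-12)

    def test_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        for cells in [(20, 80, 10, 90), (50, 950, 100, 8900), (3, 7, 11, 13)]:
            a, b, c, d = cells
            t22 = sm.stats.Table2x2(np.array([[a, b], [c, d]]))
            r = compute_ror(ContingencyTable(a, b, c, d), min_count=0)
            assert r.ror == pytest.approx(t22.oddsratio, rel=1e-12)
            # statsmodels uses z = Phi^-1(0.975) = 1.95996...; the engine
            # uses the conventional 1.96, so bounds agree to ~1e-4
            lo, hi = t22.oddsratio_confint(0.05)
            assert r.ci_low == pytest.approx(lo, rel=5e-4)
            assert r.ci_high == pytest.approx(hi, rel=5e-4)


cells = st.integers(1, 500)


class TestRorInvariants:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells, k=st.integers(2, 5))
    def test_scaling_non_case_cells_preserves_ror(self, a, b, c, d, k):
        r1 = compute_ror(ContingencyTable(a, b, c, d), min_count=0)
        r2 = compute_ror(ContingencyTable(a, k * b, c, k * d), min_count=0)
        assert r1.ror == pytest.approx(r2.ror, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_swapping_cohorts_reciprocates(self, a, b, c, d):
        r = compute_ror(ContingencyTable(a, b, c, d), min_count=0)
        s = compute_ror(ContingencyTable(c, d, a, b), min_count=0)
        assert s.ror == pytest.approx(1.0 / r.ror, rel=1e-12)
        assert s.ci_low == pytest.approx(1.0 / r.ci_high, rel=1e-9)
        assert s.ci_high == pytest.approx(1.0 / r.ci_low, rel=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells, k=st.integers(2, 6))
    def test_ci_contains_point_and_shrinks_with_size(self, a, b, c, d, k):
        r = compute_ror(ContingencyTable(a, b, c, d), min_count=0)
        assert r.ci_low <= r.ror <= r.ci_high
        bigger = compute_ror(
            ContingencyTable(k * a, k * b, k * c, k * d), min_count=0
        )
        assert bigger.ror == pytest.approx(r.ror, rel=1e-12)
        assert (bigger.ci_high / bigger.ci_low) < (r.ci_high / r.ci_low)


def events_from(spec):
    """spec: {caseid: {(pt, soc), ...}}"""
    return [AdeEvent(cid, pt, soc) for cid, pairs in spec.items()
            for pt, soc in pairs]


class TestBuildContingency:
    def test_minimal_table(self):
        events = events_from({"x": {("Nausea", "GI")}, "y": {("Rash", "Skin")}})
        t = build_contingency("Nausea", "PT", {"x"}, {"y"}, events)
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_case_counted_once_per_term(self):
        events = events_from({"x": {("Nausea", "GI")}}) * 2  # duplicated rows
        t = build_contingency("Nausea", "PT", {"x"}, {"y"}, events)
        assert t.a == 1

    def test_soc_level_counting(self):
        events = events_from({
            "x": {("Nausea", "GI"), ("Vomiting", "GI")}, "y": {("Rash", "Skin")},
        })
        t = build_contingency("GI", "SOC", {"x"}, {"y"}, events)
        assert (t.a, t.c) == (1, 0)

    def test_overlapping_cohorts_rejected(self):
        with pytest.raises(ValueError):
            build_contingency("Nausea", "PT", {"x"}, {"x"}, [])

    def test_matches_generator_bookkeeping(self, small_sim, small_dictionary):
        _, tables, truth = small_sim
        from faerspv.cases import assemble_cases, deduplicate
        from faerspv.meddra import map_events
        kept = deduplicate(tables.demo)
        cases = assemble_cases(tables, kept, set(kept))
        events, _ = map_events(cases, small_dictionary)
        target = set(truth.target_caseids)
        background = set(truth.background_caseids)
        for pt, (n_target, n_background) in truth.pt_counts.items():
            t = build_contingency(pt, "PT", target, background, events)
            assert (t.a, t.c) == (n_target, n_background)


class TestDetectSignals:
    def test_one_result_per_target_term_sorted(self):
        events = events_from({
            "t1": {("Nausea", "GI"), ("Rash", "Skin")},
            "t2": {("Nausea", "GI")},
            "c1": {("Nausea", "GI")},
            "c2": {("Rash", "Skin")},
        })
        results = detect_signals({"t1", "t2", "t3"}, {"c1", "c2"}, events,
                                 min_count=0)
        assert [r.term for r in results] == ["Nausea", "Rash"]
        assert results[0].ror == pytest.approx(2.0)
        assert results[1].ror == pytest.approx(0.5)
        rors = [r.ror for r in results if r.evaluable]
        assert rors == sorted(rors, reverse=True)

    def test_empty_target_cohort_gives_empty_list(self):
        events = events_from({"c1": {("Nausea", "GI")}})
        assert detect_signals(set(), {"c1"}, events) == []


class TestVenn:
    def test_partition_example(self):
        p = venn_partition({"A", "B", "C"}, {"B", "C", "D"})
        assert p.unique_left == {"A"}
        assert p.shared == {"B", "C"}
        assert p.unique_right == {"D"}

    def test_identical_sets_all_shared(self):
        p = venn_partition({"A"}, {"A"})
        assert p.shared == {"A"} and not p.unique_left and not p.unique_right

    def test_disjoint_sets_share_nothing(self):
        p = venn_partition({"A"}, {"B"})
        assert not p.shared


class TestUniquePtSignals:
    def test_unique_terms_routed_to_their_cohort(self):
        events = events_from({
            "o1": {("OralOnly", "X"), ("Shared", "X")},
            "s1": {("SubcutOnly", "X"), ("Shared", "X")},
            "b1": {("Shared", "X")},
        })
        partition = venn_partition({"OralOnly", "Shared"},
                                   {"SubcutOnly", "Shared"})
        oral, subcut = unique_pt_signals(
            partition, {"o1"}, {"s1"}, {"b1", "b2"}, events, min_count=0,
        )
        assert [r.term for r in oral] == ["OralOnly"]
        assert [r.term for r in subcut] == ["SubcutOnly"]


class TestRouteVsRoute:
    def test_equal_proportions_give_unit_ror(self):
        events = events_from({
            "o1": {("Nausea", "GI")}, "o2": set(),
            "s1": {("Nausea", "GI")}, "s2": set(),
        })
        r = route_vs_route_ror("Nausea", "PT", {"o1", "o2"}, {"s1", "s2"},
                               events, min_count=0)
        assert r.ror == pytest.approx(1.0)
        assert not r.is_signal

    def test_empty_cohort_not_evaluable(self):
        r = route_vs_route_ror("Nausea", "PT", set(), {"s1"}, [], min_count=0)
        assert not r.evaluable

    def test_equal_gi_shares_give_no_signal_at_study_scale(self):
        # equal GI reporting shares at realistic oral/subcutaneous cohort
        # sizes: ROR ~ 1 and the ROR_025 statistic stays below 1
        n_oral, n_sc = 2508, 16711
        a, c = round(n_oral * 0.28), round(n_sc * 0.28)
        events = []
        events += [AdeEvent(f"o{i}", "Nausea", "GI") for i in range(a)]
        events += [AdeEvent(f"s{i}", "Nausea", "GI") for i in range(c)]
        oral = {f"o{i}" for i in range(n_oral)}
        subcut = {f"s{i}" for i in range(n_sc)}
        r = route_vs_route_ror("GI", "SOC", oral, subcut, events)
        assert r.evaluable
        assert r.ror == pytest.approx(1.0, abs=0.01)
        assert r.ci_low < 1.0
        assert not r.is_signal
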