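
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

from pvsignals.reports import ReportSet, deduplicate
from pvsignals.signals import (
    ContingencyTable,
    ScreeningCriteria,
    SignalStats,
    UndefinedStatisticError,
    build_table,
    chi_square,
    detect_signals,
    evans_screen,
    lack_of_efficacy_table,
    prr,
    ror,
    ror_ci,
    summarize_classification,
    tables_for_pts,
)
from pvsignals.simulate import SimulationConfig, simulate_database

from conftest import make_report

cells = st.integers(min_value=1, max_value=2000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


class TestBuildTable:
    def test_hand_counted_toy_fixture(self, toy_set):
        t = build_table(toy_set, "ibuprofen", "pt_x")
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 5)

    def test_event_absent_everywhere(self, toy_set):
        t = build_table(toy_set, "ibuprofen", "no such pt")
        assert t.a == 0 and t.c == 0 and t.n == 10

    def test_absent_drug_warns_with_empty_target_margin(self, toy_set):
        with pytest.warns(UserWarning):
            t = build_table(toy_set, "warfarin", "pt_x")
        assert t.a == t.b == 0

    def test_requires_dedup_and_nonempty_pt(self, toy_set):
        raw = ReportSet(toy_set.reports, deduplicated=False)
        with pytest.raises(ValueError):
            build_table(raw, "ibuprofen", "pt_x")
        with pytest.raises(ValueError):
            build_table(toy_set, "ibuprofen", "")

    def test_one_pass_sweep_matches_per_pt_tables(self, toy_set):
        pts = ["pt_x", "nausea", "headache", "rash", "fatigue"]
        swept = tables_for_pts(toy_set, "ibuprofen", pts)
        for pt in pts:
            assert swept[pt] == build_table(toy_set, "ibuprofen", pt)


class TestPointStatistics:
    def test_ror_hand_values(self):
        assert ror(ContingencyTable(10, 90, 10, 890)) == pytest.approx(8900 / 900)
        assert ror(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_zero_cell_uses_haldane_correction(self):
        t = ContingencyTable(0, 10, 5, 85)
        assert ror(t) == pytest.approx((0.5 * 85.5) / (10.5 * 5.5))

    def test_prr_hand_values(self):
        assert prr(ContingencyTable(10, 90, 10, 890)) == pytest.approx(9.0)
        assert prr(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_ci_hand_value_and_bracketing(self):
        lo, hi = ror_ci(ContingencyTable(10, 90, 10, 890), z=1.96)
        assert lo == pytest.approx(4.008, abs=1e-3)
        assert hi == pytest.approx(24.393, abs=2e-3)

    @given(tables)
    def test_ci_brackets_point_estimate(self, t):
        lo, hi = ror_ci(t)
        assert lo <= ror(t) <= hi

    def test_uniform_scaling_narrows_interval_around_same_point(self):
        t = ContingencyTable(10, 90, 10, 890)
        big = ContingencyTable(1000, 9000, 1000, 89000)
        assert ror(big) == pytest.approx(ror(t))
        lo, hi = ror_ci(t)
        blo, bhi = ror_ci(big)
        assert blo > lo and bhi < hi

    def test_all_zero_margin_is_undefined(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)

    @given(tables)
    def test_monotonicity_in_a(self, t):
        bumped = ContingencyTable(t.a + 10, t.b, t.c, t.d)
        assert ror(bumped) > ror(t)
        assert prr(bumped) > prr(t)


class TestChiSquare:
    def test_hand_values_both_corrections(self):
        t = ContingencyTable(10, 90, 10, 890)
        assert chi_square(t, yates=False) == pytest.approx(36.281, abs=1e-3)
        assert chi_square(t, yates=True) == pytest.approx(31.888, abs=1e-3)

    @given(tables)
    def test_agrees_with_scipy(self, t):
        obs = [[t.a, t.b], [t.c, t.d]]
        for yates in (False, True):
            ref = chi2_contingency(obs, correction=yates)[0]
            assert chi_square(t, yates=yates) == pytest.approx(ref, rel=1e-12)

    @given(tables)
    def test_row_swap_symmetry(self, t):
        swapped = ContingencyTable(t.c, t.d, t.a, t.b)
        assert chi_square(t) == pytest.approx(chi_square(swapped), rel=1e-12)

    @given(tables)
    def test_textbook_formula_equivalence(self, t):
        a, b, c, d = t.a, t.b, t.c, t.d
        n = t.n
        ref = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi_square(t, yates=False) == pytest.approx(ref, rel=1e-9)

    def test_degenerate_margin_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            chi_square(ContingencyTable(0, 0, 5, 5))


class TestStatsmodelsOracle:
    @given(tables)
    def test_ror_matches_table2x2_oddsratio(self, t):
        ref = Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        assert ror(t) == pytest.approx(ref.oddsratio, rel=1e-12)

    @given(tables)
    def test_prr_matches_table2x2_riskratio(self, t):
        ref = Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        assert prr(t) == pytest.approx(ref.riskratio, rel=1e-12)

    @given(tables)
    def test_ci_matches_table2x2_confint(self, t):
        ref = Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        lo, hi = ror_ci(t, z=1.959963984540054)
        rlo, rhi = ref.oddsratio_confint(0.05)
        assert lo == pytest.approx(rlo, rel=1e-9)
        assert hi == pytest.approx(rhi, rel=1e-9)


def stats(n=100, chi2=50.0, prr_=5.0):
    return SignalStats(event_pt="x", n_reports=n, ror=prr_, ci_low=prr_ / 2,
                       ci_high=prr_ * 2, prr=prr_, chi2=chi2)


class TestEvansScreen:
    def test_all_thresholds_cleared(self):
        assert evans_screen(stats()) is True

    def test_chi2_at_or_below_threshold_fails(self):
        assert evans_screen(stats(chi2=3.9)) is False
        assert evans_screen(stats(chi2=4.0)) is False  # strict inequality

    def test_count_threshold(self):
        assert evans_screen(stats(n=2)) is False
        assert evans_screen(stats(n=2), ScreeningCriteria(min_reports=2)) is True

    def test_prr_threshold_strict(self):
        assert evans_screen(stats(prr_=2.0)) is False


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(
        n_reports=40_000, duplicate_fraction=0.0,
        planted_ror={"angioedema": 10.0}, seed=13,
    )
    return deduplicate(simulate_database(cfg))


class TestDetectSignals:
    def test_planted_signal_ranks_first_and_passes(self, planted):
        ranked = detect_signals(planted, "ibuprofen")
        assert ranked[0].event_pt == "angioedema"
        assert ranked[0].meets_evans
        # brute-force the statistics for the winner from raw reports
        a = sum(1 for r in planted
                if r.has_drug("ibuprofen", "PS") and "angioedema" in r.events)
        assert ranked[0].n_reports == a

    def test_loe_terms_split_out(self, planted):
        ranked = detect_signals(planted, "ibuprofen")
        assert all(s.event_pt != "drug ineffective" for s in ranked)
        loe = lack_of_efficacy_table(planted, "ibuprofen")
        assert [s.event_pt for s in loe] == ["drug ineffective"]

    def test_screening_is_a_flag_not_a_filter(self, toy_set):
        ranked = detect_signals(toy_set, "ibuprofen")
        assert ranked  # every PT reported with the drug is present
        assert {s.event_pt for s in ranked} == {"pt_x", "nausea", "headache", "rash"}

    def test_sorted_by_chi2_then_count_then_name(self, planted):
        ranked = detect_signals(planted, "ibuprofen")
        keys = [(-s.chi2, -s.n_reports, s.event_pt) for s in ranked]
        assert keys == sorted(keys)

    def test_margins_constant_across_pts(self, planted):
        ranked = detect_signals(planted, "ibuprofen")
        tabs = tables_for_pts(planted, "ibuprofen", [s.event_pt for s in ranked])
        totals = {t.n for t in tabs.values()}
        drug_margins = {t.n_target for t in tabs.values()}
        assert totals == {len(planted)}
        assert len(drug_margins) == 1


class TestSummarizeClassification:
    def test_direct_tally(self):
        sigs = [stats(n=10), stats(n=5, chi2=1.0), stats(n=5, prr_=1.0)]
        for s in sigs:
            s.meets_evans = evans_screen(s)
        assert summarize_classification(sigs) == (1, 2, 10, 10)

    def test_all_meeting_leaves_no_negatives(self):
        sigs = [stats(), stats()]
        for s in sigs:
            s.meets_evans = True
        pos, neg, *_ = summarize_classification(sigs)
        assert (pos, neg) == (2, 0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_classification([])
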