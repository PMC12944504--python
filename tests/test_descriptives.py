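import pytest

from pvsignals.descriptives import (
    FrequencyTable,
    NotDeduplicatedError,
    age_distribution,
    country_distribution,
    outcome_summary,
    percent,
    round_half_up,
    route_distribution,
    sex_distribution,
    yearly_counts,
)
from pvsignals.reports import ReportSet, deduplicate
from pvsignals.simulate import SimulationConfig, simulate_database

from conftest import make_report


def dedup_set(*reports):
    return ReportSet(list(reports), deduplicated=True)


class TestRounding:
    @pytest.mark.parametrize(
        "x,dec,expected",
        [(2.675, 2, 2.68), (23.25, 1, 23.3), (46.985, 1, 47.0), (0.215, 2, 0.22),
         (29.8634, 1, 29.9), (35.3646, 2, 35.36)],
    )
    def test_half_up(self, x, dec, expected):
        assert round_half_up(x, dec) == expected

    def test_percent_uses_denominator(self):
        assert percent(33262, 70792, 1) == 47.0


class TestFrequencyTable:
    def test_partition_table_sums_to_denominator(self):
        ft = FrequencyTable.from_counts("sex", [("F", 3), ("M", 2)], denominator=5)
        assert ft.total() == ft.denominator == 5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            FrequencyTable("x", [("a", -1, 0.0)], denominator=1)


class TestRequiresDedup:
    @pytest.mark.parametrize(
        "op",
        [yearly_counts, sex_distribution, age_distribution, route_distribution,
         outcome_summary, country_distribution],
    )
    def test_raw_sets_rejected(self, op):
        raw = ReportSet([make_report("C1")], deduplicated=False)
        with pytest.raises(NotDeduplicatedError):
            op(raw)


class TestYearlyCounts:
    def test_direct_tally(self):
        rs = dedup_set(
            make_report("A", year=2020), make_report("B", year=2020),
            make_report("C", year=2021), make_report("D", year=2021),
            make_report("E", year=2021),
        )
        assert yearly_counts(rs).counts() == {"2020": 2, "2021": 3}

    def test_empty_interior_year_zero_filled(self):
        rs = dedup_set(make_report("A", year=2019), make_report("B", year=2021))
        ft = yearly_counts(rs)
        assert ft.counts() == {"2019": 1, "2020": 0, "2021": 1}
        assert ft.total() == len(rs)

    def test_matches_generator_bookkeeping(self):
        cfg = SimulationConfig(n_reports=3000, duplicate_fraction=0.0, seed=9)
        rs = deduplicate(simulate_database(cfg))
        ft = yearly_counts(rs)
        assert ft.total() == 3000
        direct = {}
        for r in rs:
            direct[str(r.receipt_year)] = direct.get(str(r.receipt_year), 0) + 1
        assert {k: v for k, v in ft.counts().items() if v} == direct


class TestSexDistribution:
    def test_all_male_degenerate(self):
        rs = dedup_set(*[make_report(f"C{i}", sex="M") for i in range(4)])
        assert sex_distribution(rs).percents() == {"F": 0.0, "M": 100.0, "NS": 0.0}

    def test_symmetric_split(self):
        rs = dedup_set(make_report("A", sex="F"), make_report("B", sex="M"))
        assert sex_distribution(rs).percents() == {"F": 50.0, "M": 50.0, "NS": 0.0}


class TestAgeDistribution:
    def test_boundary_partition_one_per_bin(self):
        rs = dedup_set(*[
            make_report(f"C{i}", age_years=a) for i, a in enumerate([17, 18, 64, 65])
        ])
        ft = age_distribution(rs)
        assert ft.counts() == {"<18": 1, "18-64": 2, ">=65": 1, "NS": 0}
        # 64 is an adult, 65 already elderly
        assert ft.percents()["18-64"] == 50.0

    def test_missing_age_goes_to_ns(self):
        rs = dedup_set(make_report("A"), make_report("B", age_years=30.0))
        assert age_distribution(rs).counts()["NS"] == 1

    def test_overlapping_bins_rejected(self):
        rs = dedup_set(make_report("A", age_years=30.0))
        with pytest.raises(ValueError):
            age_distribution(rs, bins=(("a", 0.0, 20.0), ("b", 10.0, 30.0)))


class TestRouteDistribution:
    def test_rare_named_route_folds_into_other(self):
        # 1 of 10,000 (0.01%) is below the 0.10% threshold and folds away
        reports = [make_report(f"C{i}", routes=frozenset({"oral"})) for i in range(9999)]
        reports.append(make_report("R", routes=frozenset({"auricular"})))
        ft = route_distribution(dedup_set(*reports))
        assert ft.counts()["Other"] == 1
        assert "auricular" not in ft.counts()

    def test_share_exactly_at_threshold_is_kept(self):
        reports = [make_report(f"C{i}", routes=frozenset({"oral"})) for i in range(999)]
        reports.append(make_report("R", routes=frozenset({"auricular"})))
        ft = route_distribution(dedup_set(*reports))
        assert ft.counts()["auricular"] == 1

    def test_missingness_tokens_kept_distinct(self):
        rs = dedup_set(
            make_report("A", routes=frozenset({"unspecified"})),
            make_report("B", routes=frozenset()),
            make_report("C", routes=frozenset({"oral"})),
        )
        counts = route_distribution(rs).counts()
        assert counts["Unspecified"] == 1 and counts["Unknown"] == 1
        assert counts["oral"] == 1

    def test_multi_route_report_counts_once_by_precedence(self):
        rs = dedup_set(make_report("A", routes=frozenset({"intravenous", "oral"})))
        counts = route_distribution(rs).counts()
        assert counts["oral"] == 1 and sum(counts.values()) == 1

    def test_categories_partition_reports(self):
        cfg = SimulationConfig(n_reports=5000, duplicate_fraction=0.0, seed=4)
        rs = deduplicate(simulate_database(cfg))
        assert route_distribution(rs).total() == len(rs)


class TestOutcomeSummary:
    def test_multi_outcome_case_counts_once_as_unfavorable(self):
        rs = dedup_set(make_report("A", outcomes=frozenset({"HO", "LT"})))
        ft, unfavorable = outcome_summary(rs)
        assert ft.counts()["HO"] == 1 and ft.counts()["LT"] == 1
        assert unfavorable == 1

    def test_other_alone_is_not_unfavorable(self):
        rs = dedup_set(*[
            make_report(f"C{i}", outcomes=frozenset({"OT"})) for i in range(3)
        ])
        _, unfavorable = outcome_summary(rs)
        assert unfavorable == 0

    def test_percentages_are_of_all_reports(self):
        rs = dedup_set(
            make_report("A", outcomes=frozenset({"DE"})),
            make_report("B"), make_report("C"), make_report("D"),
        )
        ft, _ = outcome_summary(rs)
        assert ft.percents()["DE"] == 25.0


class TestCountryDistribution:
    def test_aggregation_rule(self):
        rs = dedup_set(
            make_report("A", country="US"), make_report("B", country="US"),
            make_report("C", country="US"), make_report("D", country="GB"),
            make_report("E", country="GB"), make_report("F"),
        )
        ft = country_distribution(rs, top_n=1)
        assert ft.counts() == {"US": 3, "RoW": 2, "NS": 1}
        assert ft.total() == 6

    def test_top_n_beyond_distinct_countries_leaves_empty_rest(self):
        rs = dedup_set(make_report("A", country="US"), make_report("B", country="GB"))
        assert country_distribution(rs, top_n=10).counts()["RoW"] == 0

    def test_distinct_countries_match_generator_pool_usage(self):
        cfg = SimulationConfig(n_reports=4000, duplicate_fraction=0.0, seed=2)
        rs = deduplicate(simulate_database(cfg))
        seen = {r.country for r in rs} - {"NS"}
        ft = country_distribution(rs, top_n=len(cfg.country_weights))
        listed = {label for label, c, _ in ft.rows if label not in ("RoW", "NS") and c}
        assert listed == seen
        assert ft.total() == len(rs)
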