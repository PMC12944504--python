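"""Disproportionality analysis: 2×2 tables, ROR, PRR, χ², Evans screening.

Signal detection in spontaneous-report databases compares how often an
event is reported with the drug of interest against how often it is
reported with everything else, through the report-level contingency table

    =============  =========  ============
    .              event      no event
    =============  =========  ============
    target drug    a          b
    other drugs    c          d
    =============  =========  ============

The reporting odds ratio ROR = ad/bc (Wald 95% CI on the log scale with
SE = sqrt(1/a + 1/b + 1/c + 1/d)) quantifies strength; the proportional
reporting ratio PRR = [a/(a+b)] / [c/(c+d)] and the Pearson χ² (optionally
Yates-corrected) feed Evans' screening rule: a drug–event pair is flagged
when the report count, PRR and χ² all clear fixed thresholds. A flagged
pair is a hypothesis for clinical review, not proof of causality.

Counting unit is the deduplicated report: one case contributes once to
each margin, and repeated PT mentions within a report count once.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .reports import ReportSet, normalize_drug_name

#: z-quantile for the 95% Wald interval.
Z95 = 1.959964


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for this table (degenerate margin)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2×2 cells for one drug–event pair.

    a: target-drug reports mentioning the event; b: target-drug reports
    without it; c/d: the same split over all other reports.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_target(self) -> int:
        return self.a + self.b

    def corrected(self) -> "_Cells":
        """Haldane–Anscombe cells: add 0.5 to all four iff any cell is zero."""
        if min(self.a, self.b, self.c, self.d) == 0:
            return _Cells(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return _Cells(float(self.a), float(self.b), float(self.c), float(self.d))


@dataclass(frozen=True)
class _Cells:
    a: float
    b: float
    c: float
    d: float


def build_table(rs: ReportSet, drug: str, event_pt: str) -> ContingencyTable:
    """Count the 2×2 cells for *drug* (as primary suspect) vs *event_pt*.

    The background (c, d) is every report in *rs* not naming the drug as
    primary suspect. An absent drug yields a table with a = b = 0, with a
    warning.
    """
    if not rs.deduplicated:
        raise ValueError("build_table requires a deduplicated ReportSet")
    if not event_pt:
        raise ValueError("event_pt must be nonempty")
    want = normalize_drug_name(drug)
    pt = " ".join(event_pt.split()).casefold()
    a = b = c = d = 0
    for r in rs:
        target = r.has_drug(want, role="PS")
        has_event = pt in r.events
        if target:
            if has_event:
                a += 1
            else:
                b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    if a + b == 0:
        warnings.warn(f"drug {drug!r} has no primary-suspect reports in this set")
    return ContingencyTable(a, b, c, d)


def tables_for_pts(rs: ReportSet, drug: str, pts) -> dict[str, ContingencyTable]:
    """One-pass construction of the 2×2 table for every PT in *pts*.

    Equivalent to calling :func:`build_table` per PT, but sweeps the
    report set once, which matters when ranking hundreds of PTs over
    large databases.
    """
    if not rs.deduplicated:
        raise ValueError("tables_for_pts requires a deduplicated ReportSet")
    want = normalize_drug_name(drug)
    pts = list(pts)
    ptset = set(pts)
    n_target = n_total = 0
    a_counts = {pt: 0 for pt in pts}
    c_counts = {pt: 0 for pt in pts}
    for r in rs:
        n_total += 1
        target = r.has_drug(want, role="PS")
        if target:
            n_target += 1
        bucket = a_counts if target else c_counts
        for pt in r.events & ptset:
            bucket[pt] += 1
    n_bg = n_total - n_target
    return {
        pt: ContingencyTable(
            a_counts[pt], n_target - a_counts[pt],
            c_counts[pt], n_bg - c_counts[pt],
        )
        for pt in pts
    }


def ror(t: ContingencyTable) -> float:
    """Reporting odds ratio ad/bc on (possibly continuity-corrected) cells."""
    x = t.corrected()
    if x.b * x.c == 0:
        raise UndefinedStatisticError(f"ROR undefined for cells {t}")
    return (x.a * x.d) / (x.b * x.c)


def ror_ci(t: ContingencyTable, z: float = Z95) -> tuple[float, float]:
    """Wald 95% CI: exp(ln ROR ∓ z·SE), SE = sqrt(Σ 1/cell), same cells as ror."""
    if z <= 0:
        raise ValueError("z must be positive")
    x = t.corrected()
    if min(x.a, x.b, x.c, x.d) == 0:
        raise UndefinedStatisticError(f"ROR CI undefined for cells {t}")
    point = (x.a * x.d) / (x.b * x.c)
    se = math.sqrt(1 / x.a + 1 / x.b + 1 / x.c + 1 / x.d)
    return point * math.exp(-z * se), point * math.exp(z * se)


def prr(t: ContingencyTable) -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)] on corrected cells."""
    x = t.corrected()
    if x.a + x.b == 0 or x.c == 0:
        raise UndefinedStatisticError(f"PRR undefined for cells {t}")
    return (x.a / (x.a + x.b)) / (x.c / (x.c + x.d))


def chi_square(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson χ² on the raw cells, optionally with Yates' continuity correction.

    Σ (max(|O−E|−h, 0))² / E over the four cells, h = 0.5 under Yates;
    expected counts from the margins. Degenerate margins (an all-zero row
    or column) leave the statistic undefined.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise UndefinedStatisticError(f"chi-square undefined for cells {t}")
    h = 0.5 if yates else 0.0
    stat = 0.0
    for o, e in ((a, r1 * c1 / n), (b, r1 * c2 / n), (c, r2 * c1 / n), (d, r2 * c2 / n)):
        dev = max(abs(o - e) - h, 0.0)
        stat += dev * dev / e
    return stat


@dataclass(frozen=True)
class ScreeningCriteria:
    """Evans screening thresholds and CI settings.

    A pair is flagged when n_reports ≥ min_reports, χ² > chi2_threshold and
    PRR > prr_threshold. ``loe_terms`` lists lack-of-efficacy PTs that are
    tabulated separately from ADR signals (therapeutic failure, not harm).
    """

    min_reports: int = 3
    chi2_threshold: float = 4.0
    prr_threshold: float = 2.0
    z: float = Z95
    yates: bool = True
    loe_terms: frozenset = frozenset({"drug ineffective"})

    def __post_init__(self):
        if self.min_reports <= 0 or self.chi2_threshold <= 0 or self.prr_threshold <= 0:
            raise ValueError("screening thresholds must be positive")
        if self.z <= 0:
            raise ValueError("z must be positive")
        object.__setattr__(self, "loe_terms", frozenset(self.loe_terms))


@dataclass
class SignalStats:
    """Full disproportionality record for one event PT."""

    event_pt: str
    n_reports: int
    ror: float
    ci_low: float
    ci_high: float
    prr: float
    chi2: float
    yates: bool = True
    meets_evans: bool = False

    def __post_init__(self):
        if not (self.ci_low <= self.ror <= self.ci_high):
            raise ValueError(
                f"{self.event_pt}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket ROR {self.ror}"
            )
        if min(self.ror, self.prr, self.chi2) < 0:
            raise ValueError(f"{self.event_pt}: negative statistic")


def evans_screen(s: SignalStats, crit: ScreeningCriteria = ScreeningCriteria()) -> bool:
    """True iff the pair clears all three Evans thresholds."""
    return (
        s.n_reports >= crit.min_reports
        and s.chi2 > crit.chi2_threshold
        and s.prr > crit.prr_threshold
    )


def _stats_from_table(pt: str, t: ContingencyTable, crit: ScreeningCriteria) -> SignalStats:
    s = SignalStats(
        event_pt=pt,
        n_reports=t.a,
        ror=ror(t),
        ci_low=ror_ci(t, crit.z)[0],
        ci_high=ror_ci(t, crit.z)[1],
        prr=prr(t),
        chi2=chi_square(t, yates=crit.yates),
        yates=crit.yates,
    )
    s.meets_evans = evans_screen(s, crit)
    return s


def _target_pts(rs: ReportSet, drug: str) -> set[str]:
    want = normalize_drug_name(drug)
    pts: set[str] = set()
    for r in rs:
        if r.has_drug(want, role="PS"):
            pts |= r.events
    return pts


def detect_signals(
    rs: ReportSet, drug: str, crit: ScreeningCriteria = ScreeningCriteria()
) -> list[SignalStats]:
    """Rank every PT reported with the drug by χ², with Evans verdicts.

    One SignalStats per distinct PT among the drug's primary-suspect
    reports, excluding lack-of-efficacy terms (see
    :func:`lack_of_efficacy_table` for those). Sorted by χ² descending,
    ties by report count descending then PT ascending. Screening is a
    flag, not a filter: pairs failing the thresholds stay in the list.
    """
    if not rs.deduplicated:
        raise ValueError("detect_signals requires a deduplicated ReportSet")
    pts = sorted(_target_pts(rs, drug) - set(crit.loe_terms))
    tables = tables_for_pts(rs, drug, pts)
    out = [_stats_from_table(pt, tables[pt], crit) for pt in pts]
    out.sort(key=lambda s: (-s.chi2, -s.n_reports, s.event_pt))
    return out


def lack_of_efficacy_table(
    rs: ReportSet, drug: str, crit: ScreeningCriteria = ScreeningCriteria()
) -> list[SignalStats]:
    """Disproportionality statistics for the lack-of-efficacy PTs only.

    Therapeutic-failure reports describe effectiveness, not harm, so they
    are tabulated apart from the ADR signal ranking.
    """
    if not rs.deduplicated:
        raise ValueError("lack_of_efficacy_table requires a deduplicated ReportSet")
    pts = sorted(_target_pts(rs, drug) & set(crit.loe_terms))
    tables = tables_for_pts(rs, drug, pts)
    return [_stats_from_table(pt, tables[pt], crit) for pt in pts]


def summarize_classification(signals: list[SignalStats]) -> tuple[int, int, int, int]:
    """Split signals on the Evans verdict.

    Returns (positive_count, negative_count, positive_report_sum,
    negative_report_sum), where "negative" means not meeting the screening
    criteria (sometimes loosely called false signals).
    """
    if not signals:
        raise ValueError("summarize_classification needs at least one signal")
    pos = [s for s in signals if s.meets_evans]
    neg = [s for s in signals if not s.meets_evans]
    return (
        len(pos),
        len(neg),
        sum(s.n_reports for s in pos),
        sum(s.n_reports for s in neg),
    )
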