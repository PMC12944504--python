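"""Descriptive epidemiology of a deduplicated report set.

Yearly trend, country of origin, sex, age group, administration route and
outcome tabulations, with the missing-data and bucketing conventions used
in FAERS-style descriptive tables: a single "NS" bucket per dimension for
unrecorded values, rare named routes collapsed into "Other", and half-up
percentage rounding at a stated number of decimals.

All operations require a deduplicated set — descriptive denominators are
unique cases, and running them on raw rows would double-count follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .reports import NS, UNFAVORABLE_OUTCOMES, ReportSet


class NotDeduplicatedError(ValueError):
    """Descriptive statistics need unique cases; deduplicate first."""


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero (half-up), as printed tables do.

    Binary-float artifacts are neutralized by quantizing the shortest repr
    of *x* rather than its binary expansion, so e.g. 2.675 → 2.68 at two
    decimals.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    """100·count/denominator, rounded half-up to *decimals*."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * count / denominator, decimals)


@dataclass
class FrequencyTable:
    """Counts and percentages of one descriptive dimension.

    ``rows`` is an ordered list of ``(label, count, percent)``;
    percentages are of ``denominator`` and rounded half-up to
    ``decimals``. When the dimension partitions reports, counts sum to
    the denominator.
    """

    dimension: str
    rows: list = field(default_factory=list)
    denominator: int = 0
    decimals: int = 1

    def __post_init__(self):
        for label, count, _pct in self.rows:
            if count < 0:
                raise ValueError(f"{self.dimension}: negative count for {label!r}")

    @classmethod
    def from_counts(cls, dimension, counts, denominator, decimals=1):
        """Build a table from ordered ``(label, count)`` pairs."""
        rows = [
            (label, int(c), percent(int(c), denominator, decimals))
            for label, c in counts
        ]
        return cls(dimension=dimension, rows=rows, denominator=denominator,
                   decimals=decimals)

    def counts(self) -> dict:
        return {label: c for label, c, _ in self.rows}

    def percents(self) -> dict:
        return {label: p for label, _, p in self.rows}

    def total(self) -> int:
        return sum(c for _, c, _ in self.rows)

    def to_records(self) -> list[dict]:
        return [
            {"category": label, "count": c, "percent": p}
            for label, c, p in self.rows
        ]


def _require_dedup(rs: ReportSet) -> None:
    if not rs.deduplicated:
        raise NotDeduplicatedError(
            "descriptive statistics require a deduplicated ReportSet"
        )


def yearly_counts(rs: ReportSet) -> FrequencyTable:
    """Reports per receipt year over the observed span, zero-filled."""
    _require_dedup(rs)
    tally: dict[int, int] = {}
    for r in rs:
        tally[r.receipt_year] = tally.get(r.receipt_year, 0) + 1
    if not tally:
        return FrequencyTable("year", [], 0)
    lo, hi = min(tally), max(tally)
    counts = [(str(y), tally.get(y, 0)) for y in range(lo, hi + 1)]
    return FrequencyTable.from_counts("year", counts, denominator=len(rs))


def sex_distribution(rs: ReportSet) -> FrequencyTable:
    """F / M / NS shares of all reports (one decimal)."""
    _require_dedup(rs)
    tally = {"F": 0, "M": 0, NS: 0}
    for r in rs:
        tally[r.sex] += 1
    return FrequencyTable.from_counts(
        "sex", [(k, tally[k]) for k in ("F", "M", NS)], denominator=len(rs)
    )


#: Default age groups: children/adolescents, adults, elderly.
DEFAULT_AGE_BINS = (("<18", 0.0, 18.0), ("18-64", 18.0, 65.0), (">=65", 65.0, None))


def age_distribution(rs: ReportSet, bins=DEFAULT_AGE_BINS) -> FrequencyTable:
    """Age-group shares with an NS row for reports lacking age.

    ``bins`` is an ordered sequence of ``(label, lo, hi)`` half-open
    intervals [lo, hi); ``hi=None`` means unbounded, so with the defaults
    age 65 falls in the elderly group. Bins must not overlap.
    """
    _require_dedup(rs)
    for (l1, lo1, hi1), (l2, lo2, hi2) in zip(bins, bins[1:]):
        if hi1 is None or lo2 < hi1:
            raise ValueError(f"age bins {l1!r} and {l2!r} overlap or are unordered")
    tally = {label: 0 for label, _, _ in bins}
    tally[NS] = 0
    for r in rs:
        if r.age_years is None:
            tally[NS] += 1
            continue
        for label, lo, hi in bins:
            if r.age_years >= lo and (hi is None or r.age_years < hi):
                tally[label] += 1
                break
        else:
            tally[NS] += 1  # age outside every bin: report it as unclassed
    order = [label for label, _, _ in bins] + [NS]
    return FrequencyTable.from_counts(
        "age_group", [(k, tally[k]) for k in order], denominator=len(rs)
    )


#: Highest-precedence named routes, in conventional table order; any other
#: named route follows alphabetically.
ROUTE_PRECEDENCE = ("oral", "transplacental", "intravenous")

UNSPECIFIED = "Unspecified"
UNKNOWN = "Unknown"
OTHER = "Other"


def _route_category(r) -> str:
    named = sorted(t for t in r.routes if t not in ("unspecified", "unknown"))
    if named:
        for pref in ROUTE_PRECEDENCE:
            if pref in named:
                return pref
        return named[0]
    if "unspecified" in r.routes:
        return UNSPECIFIED
    return UNKNOWN  # empty set or explicit "unknown": route not reported


def route_distribution(rs: ReportSet, other_threshold: float = 0.001) -> FrequencyTable:
    """One route category per report; rare named routes fold into "Other".

    Each report counts once, under its highest-precedence recorded named
    route; reports whose route field holds only a missingness token count
    under "Unspecified" or "Unknown". Named categories whose share of the
    denominator is below ``other_threshold`` (default 0.10%) are collapsed
    into "Other". Percentages use two decimals, as route tables
    conventionally print. Counts always partition the report set.
    """
    _require_dedup(rs)
    tally: dict[str, int] = {}
    for r in rs:
        cat = _route_category(r)
        tally[cat] = tally.get(cat, 0) + 1
    total = len(rs)
    named = {
        k: v for k, v in tally.items() if k not in (UNSPECIFIED, UNKNOWN)
    }
    kept, other = {}, 0
    for k, v in named.items():
        if total and v / total < other_threshold:
            other += v
        else:
            kept[k] = v
    order = sorted(kept, key=lambda k: (-kept[k], k))
    counts = [(k, kept[k]) for k in order]
    counts.append((UNSPECIFIED, tally.get(UNSPECIFIED, 0)))
    counts.append((UNKNOWN, tally.get(UNKNOWN, 0)))
    counts.append((OTHER, other))
    return FrequencyTable.from_counts("route", counts, denominator=total, decimals=2)


#: Outcome rows in conventional severity order.
OUTCOME_ORDER = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


def outcome_summary(rs: ReportSet) -> tuple[FrequencyTable, int]:
    """Per-outcome counts plus the number of cases with any unfavorable outcome.

    A case can carry several outcome codes, so outcome rows do not
    partition the set and need not sum to the total; percentages are of
    all reports. The unfavorable count tallies cases whose outcomes
    intersect {DE, LT, HO, DS, CA, RI} — "other" alone is not unfavorable.
    """
    _require_dedup(rs)
    tally = {c: 0 for c in OUTCOME_ORDER}
    unfavorable = 0
    for r in rs:
        for c in r.outcomes:
            tally[c] += 1
        if r.outcomes & UNFAVORABLE_OUTCOMES:
            unfavorable += 1
    table = FrequencyTable.from_counts(
        "outcome", [(c, tally[c]) for c in OUTCOME_ORDER], denominator=len(rs)
    )
    return table, unfavorable


ROW = "RoW"


def country_distribution(rs: ReportSet, top_n: int = 10) -> FrequencyTable:
    """Top-N countries by count, a rest-of-the-world row, and an NS row."""
    _require_dedup(rs)
    tally: dict[str, int] = {}
    ns = 0
    for r in rs:
        if r.country == NS:
            ns += 1
        else:
            tally[r.country] = tally.get(r.country, 0) + 1
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:top_n]
    rest = sum(c for _, c in ranked[top_n:])
    counts = top + [(ROW, rest), (NS, ns)]
    return FrequencyTable.from_counts("country", counts, denominator=len(rs))
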