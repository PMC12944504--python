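"""Individual case safety reports: data model, flat-file I/O, deduplication.

A spontaneous reporting system stores one row per *report version*: a case
(patient episode) may be submitted several times as follow-up information
arrives, each version sharing the case identifier but carrying a larger
version identifier.  Signal detection must count each case once, so the
canonical preprocessing steps are (i) keep only the most recent version of
each case and (ii) restrict to reports naming the drug of interest as the
primary suspect (role ``PS``).

The flat dialect read and written here is a UTF-8 TSV/CSV with one report
per row and ``;``-separated multi-valued fields — the shape of an
OpenVigil-style FAERS extract.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

#: Valid outcome codes: death, life-threatening, hospitalization,
#: disability, congenital anomaly, required intervention, other.
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: Outcome codes counted as unfavorable (everything but "other").
UNFAVORABLE_OUTCOMES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI"})

#: Drug roles: primary suspect, secondary suspect, concomitant, interacting.
DRUG_ROLES = frozenset({"PS", "SS", "C", "I"})

SEX_CODES = frozenset({"F", "M", "NS"})

#: Sentinel for "not specified" in sex and country fields.
NS = "NS"

MAX_AGE_YEARS = 122.0

#: Column order of the flat dialect.
DIALECT_COLUMNS = (
    "case_id",
    "primary_id",
    "year",
    "country",
    "sex",
    "age",
    "routes",
    "outcomes",
    "drugs",
    "events",
)

LIST_SEP = ";"


class ReportError(ValueError):
    """Invalid report content (field-level invariant violated)."""


class DialectError(ValueError):
    """Malformed input file; carries all row-level errors found."""

    def __init__(self, message: str, row_errors: Sequence[str] = ()):
        super().__init__(message)
        self.row_errors = list(row_errors)


def normalize_drug_name(name: str) -> str:
    """Trim, collapse internal whitespace and case-fold a drug name.

    Matching is done at the active-substance level; no synonym expansion.
    """
    return " ".join(name.split()).casefold()


def _normalize_token(tok: str) -> str:
    return " ".join(tok.split()).casefold()


@dataclass
class SafetyReport:
    """One spontaneous adverse-event report (a single version of a case).

    Parameters
    ----------
    case_id : str
        Opaque case identifier; shared by all versions of a case.
    version_id : str
        Orderable version identifier within the case; larger = more recent.
        Compared numerically when both sides parse as integers, else
        lexicographically.
    receipt_year : int
        Calendar year the report was received.
    country : str
        ISO-like country token, or ``"NS"`` when not specified.
    sex : str
        ``"F"``, ``"M"`` or ``"NS"``.
    age_years : float or None
        Patient age in years, if recorded; constrained to [0, 122].
    routes : frozenset of str
        Normalized administration-route tokens (possibly empty; the token
        ``"unspecified"`` is itself a recorded value, an empty set means the
        route field was not reported at all).
    outcomes : frozenset of str
        Subset of the seven outcome codes.
    drugs : tuple of (str, str)
        ``(normalized_drug_name, role)`` pairs, role in {PS, SS, C, I}.
    events : frozenset of str
        Nonempty set of normalized preferred-term (PT) event labels.
        Repeated PT tokens within one report count once.
    """

    case_id: str
    version_id: str
    receipt_year: int
    country: str = NS
    sex: str = NS
    age_years: float | None = None
    routes: frozenset = frozenset()
    outcomes: frozenset = frozenset()
    drugs: tuple = ()
    events: frozenset = frozenset()

    def __post_init__(self):
        if not self.case_id:
            raise ReportError("case_id must be nonempty")
        if not self.version_id:
            raise ReportError("version_id must be nonempty")
        if not self.events:
            raise ReportError(f"case {self.case_id}: events must be nonempty")
        if self.sex not in SEX_CODES:
            raise ReportError(f"case {self.case_id}: invalid sex {self.sex!r}")
        if self.age_years is not None and not (0 <= self.age_years <= MAX_AGE_YEARS):
            raise ReportError(
                f"case {self.case_id}: age {self.age_years} outside [0, {MAX_AGE_YEARS}]"
            )
        bad = set(self.outcomes) - OUTCOME_CODES
        if bad:
            raise ReportError(f"case {self.case_id}: unknown outcome codes {sorted(bad)}")
        for name, role in self.drugs:
            if role not in DRUG_ROLES:
                raise ReportError(f"case {self.case_id}: unknown drug role {role!r}")
        self.routes = frozenset(self.routes)
        self.outcomes = frozenset(self.outcomes)
        self.events = frozenset(self.events)
        self.drugs = tuple(self.drugs)

    def has_drug(self, drug_name: str, role: str | None = None) -> bool:
        """True if the report lists *drug_name* (optionally with *role*)."""
        want = normalize_drug_name(drug_name)
        return any(
            name == want and (role is None or r == role) for name, r in self.drugs
        )

    @property
    def version_key(self):
        """Sort key for version comparison: numeric if possible, else lexical."""
        return _version_key(self.version_id)


def _version_key(version_id: str):
    try:
        return (0, int(version_id), "")
    except ValueError:
        return (1, 0, version_id)


@dataclass
class ReportSet:
    """An ordered collection of safety reports.

    ``deduplicated`` is True once :func:`deduplicate` has run, in which case
    all case_id values are unique. ``target_drug`` records the normalized
    drug name the set was filtered on, if any.
    """

    reports: list = field(default_factory=list)
    deduplicated: bool = False
    target_drug: str | None = None

    def __post_init__(self):
        self.reports = list(self.reports)
        if self.deduplicated:
            ids = [r.case_id for r in self.reports]
            if len(ids) != len(set(ids)):
                raise ReportError("deduplicated ReportSet has repeated case_ids")

    def __len__(self):
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)


def deduplicate(rs: ReportSet) -> ReportSet:
    """Keep only the most recent version of each case.

    For every case_id the report with the maximal version_id survives;
    ties on version_id are broken by last occurrence in input order.
    Surviving cases keep the input order of their first appearance.
    Idempotent; never increases the report count.
    """
    best: dict[str, SafetyReport] = {}
    order: list[str] = []
    for rep in rs.reports:
        cur = best.get(rep.case_id)
        if cur is None:
            best[rep.case_id] = rep
            order.append(rep.case_id)
        elif rep.version_key >= cur.version_key:
            # >= : later occurrence wins a version tie
            best[rep.case_id] = rep
    return ReportSet(
        reports=[best[cid] for cid in order],
        deduplicated=True,
        target_drug=rs.target_drug,
    )


def filter_primary_suspect(rs: ReportSet, drug_name: str) -> ReportSet:
    """Retain reports naming *drug_name* with the primary-suspect role.

    Matching is case-insensitive exact on the normalized name. An empty
    result is returned as-is (callers may warn); it is not an error.
    """
    if not drug_name:
        raise ValueError("drug_name must be nonempty")
    want = normalize_drug_name(drug_name)
    kept = [r for r in rs.reports if r.has_drug(want, role="PS")]
    return ReportSet(reports=kept, deduplicated=rs.deduplicated, target_drug=want)


# ---------------------------------------------------------------------------
# Flat-file dialect
# ---------------------------------------------------------------------------

def _split_list(cell: str) -> list[str]:
    return [t for t in (p.strip() for p in cell.split(LIST_SEP)) if t]


def _parse_row(row: dict, lineno: int) -> SafetyReport:
    case_id = row["case_id"].strip()
    version_id = row["primary_id"].strip()
    year_s = row["year"].strip()
    if not year_s:
        raise ReportError("missing year")
    receipt_year = int(year_s)
    country = row["country"].strip() or NS
    sex = row["sex"].strip().upper() or NS
    age_s = row["age"].strip()
    age = float(age_s) if age_s else None
    routes = frozenset(_normalize_token(t) for t in _split_list(row["routes"]))
    outcomes = frozenset(t.upper() for t in _split_list(row["outcomes"]))
    drugs = []
    for entry in _split_list(row["drugs"]):
        name, sep, role = entry.rpartition(":")
        if not sep:
            raise ReportError(f"drug entry {entry!r} lacks a ':role' suffix")
        drugs.append((normalize_drug_name(name), role.strip().upper()))
    events = frozenset(_normalize_token(t) for t in _split_list(row["events"]))
    return SafetyReport(
        case_id=case_id,
        version_id=version_id,
        receipt_year=receipt_year,
        country=country,
        sex=sex,
        age_years=age,
        routes=routes,
        outcomes=outcomes,
        drugs=tuple(drugs),
        events=events,
    )


def read_reports(path: str | Path, dialect: str = "tsv") -> ReportSet:
    """Read a flat report extract into a :class:`ReportSet`.

    ``dialect`` is ``"tsv"`` or ``"csv"``. The header row must list exactly
    the dialect columns. Row-level problems are collected and raised
    together as a :class:`DialectError` naming each offending line.
    """
    delim = {"tsv": "\t", "csv": ","}[dialect]
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise DialectError(f"{path}: empty file")
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    if tuple(reader.fieldnames or ()) != DIALECT_COLUMNS:
        raise DialectError(
            f"{path}: header {reader.fieldnames!r} does not match expected "
            f"columns {list(DIALECT_COLUMNS)!r}"
        )
    reports: list[SafetyReport] = []
    errors: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        if any(v is None for v in row.values()):
            errors.append(f"line {lineno}: wrong field count")
            continue
        try:
            reports.append(_parse_row(row, lineno))
        except (ReportError, ValueError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise DialectError(
            f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors),
            row_errors=errors,
        )
    if not reports:
        raise DialectError(f"{path}: no data rows")
    return ReportSet(reports=reports, deduplicated=False)


def _format_age(age: float | None) -> str:
    if age is None:
        return ""
    if float(age).is_integer():
        return str(int(age))
    return repr(float(age))


def write_reports(rs: ReportSet, path: str | Path, dialect: str = "tsv") -> None:
    """Write a ReportSet in the flat dialect (inverse of :func:`read_reports`).

    Multi-valued fields are emitted in sorted order so output is
    deterministic and write → read → write is byte-identical.
    """
    delim = {"tsv": "\t", "csv": ","}[dialect]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(DIALECT_COLUMNS)
        for r in rs.reports:
            writer.writerow(
                [
                    r.case_id,
                    r.version_id,
                    str(r.receipt_year),
                    r.country,
                    r.sex,
                    _format_age(r.age_years),
                    LIST_SEP.join(sorted(r.routes)),
                    LIST_SEP.join(sorted(r.outcomes)),
                    LIST_SEP.join(f"{n}:{role}" for n, role in r.drugs),
                    LIST_SEP.join(sorted(r.events)),
                ]
            )
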