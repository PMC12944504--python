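"""Consistency checks for published disproportionality tuples.

Published signal tables print (report count a, ROR, 95% CI, sometimes PRR
and χ²) but rarely the full 2×2 cells. Two exact algebraic facts make such
tuples verifiable anyway:

* **Margin identity.** With b = n_drug − a and d/c = ROR·b/a (which is just
  the definition of the odds ratio), PRR = (a/n_drug)·(1 + ROR·b/a) —
  independent of the background size. A printed PRR inconsistent with the
  printed (a, ROR) under this identity cannot come from any 2×2 table with
  the stated drug margin.

* **CI inversion.** The Wald interval width fixes SE² = Σ 1/cell, so
  SE² − 1/a − 1/b = 1/c + 1/d. Substituting d = ROR·b·c/a gives a linear
  equation in 1/c with the closed-form root c = (1 + a/(ROR·b)) / S where
  S = SE² − 1/a − 1/b. This recovers the hidden background cells (up to CI
  rounding, to which c is quite sensitive) and lets printed χ² values be
  recomputed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .signals import Z95, ContingencyTable, chi_square, ror as _ror, prr as _prr


class InfeasibleTupleError(ValueError):
    """The printed tuple is inconsistent with any 2×2 table."""


@dataclass(frozen=True)
class PublishedTuple:
    """One printed signal row: event, report count, ROR with CI, PRR, χ²."""

    event_pt: str
    a: int
    n_drug: int
    ror: float
    ci_low: float
    ci_high: float
    prr: float | None = None
    chi2: float | None = None

    def __post_init__(self):
        if not 0 < self.a < self.n_drug:
            raise ValueError(f"{self.event_pt}: need 0 < a < n_drug")
        if not self.ci_low <= self.ror <= self.ci_high:
            raise ValueError(f"{self.event_pt}: CI does not bracket ROR")


def implied_prr(a: int, n_drug: int, ror: float) -> float:
    """The PRR forced by the drug margin and the ROR.

    PRR = (a/n_drug)·(1 + ROR·b/a) with b = n_drug − a; exact for any
    table with those margins, whatever the background size.
    """
    if not 0 < a < n_drug:
        raise ValueError("need 0 < a < n_drug")
    if ror <= 0:
        raise ValueError("ror must be positive")
    b = n_drug - a
    return (a / n_drug) * (1.0 + ror * b / a)


def invert_ror(pt: PublishedTuple, z: float = Z95) -> ContingencyTable:
    """Recover the hidden (c, d) cells from a printed (a, n_drug, ROR, CI).

    Solves 1/c + 1/d = SE² − 1/a − 1/b with d = ROR·b·c/a in closed form
    and rounds to integers. Raises :class:`InfeasibleTupleError` when the
    printed interval is too narrow to admit any background (SE² ≤ 1/a+1/b)
    or has zero width.
    """
    if pt.ci_high <= pt.ci_low:
        raise InfeasibleTupleError(f"{pt.event_pt}: CI has zero or negative width")
    a, b = pt.a, pt.n_drug - pt.a
    se2 = (math.log(pt.ci_high / pt.ci_low) / (2.0 * z)) ** 2
    s = se2 - 1.0 / a - 1.0 / b
    if s <= 0:
        raise InfeasibleTupleError(
            f"{pt.event_pt}: SE^2 {se2:.3e} does not exceed 1/a + 1/b "
            f"{1 / a + 1 / b:.3e} (deficit {1 / a + 1 / b - se2:.3e})"
        )
    c = (1.0 + a / (pt.ror * b)) / s
    d = pt.ror * b * c / a
    ci, di = round(c), round(d)
    if ci < 1 or di < 1:
        raise InfeasibleTupleError(f"{pt.event_pt}: no positive integer root")
    return ContingencyTable(a, b, ci, di)


def consistency_report(pts: list[PublishedTuple], z: float = Z95,
                       prr_rtol: float = 0.01, chi2_rtol: float = 0.02) -> list[dict]:
    """Machine-readable verdicts for a list of published tuples.

    Per tuple: the margin-implied PRR vs the printed one (relative
    deviation, checked at ``prr_rtol``), the reconstructed table and χ²
    under both Yates settings vs the printed χ² (checked at
    ``chi2_rtol`` against the nearer of the two), and feasibility flags.
    Infeasible tuples are reported, not raised.
    """
    out = []
    for pt in pts:
        row = {
            "event_pt": pt.event_pt,
            "a": pt.a,
            "n_drug": pt.n_drug,
            "ror": pt.ror,
            "prr_printed": pt.prr,
            "prr_implied": implied_prr(pt.a, pt.n_drug, pt.ror),
            "prr_rel_dev": None,
            "prr_ok": None,
            "feasible": True,
            "c": None,
            "d": None,
            "chi2_printed": pt.chi2,
            "chi2_raw": None,
            "chi2_yates": None,
            "chi2_rel_dev": None,
            "chi2_ok": None,
            "prr_rtol": prr_rtol,
            "chi2_rtol": chi2_rtol,
        }
        if pt.prr is not None:
            dev = abs(row["prr_implied"] - pt.prr) / pt.prr
            row["prr_rel_dev"] = dev
            row["prr_ok"] = dev <= prr_rtol
        try:
            t = invert_ror(pt, z=z)
        except InfeasibleTupleError as exc:
            row["feasible"] = False
            row["infeasibility"] = str(exc)
        else:
            row["c"], row["d"] = t.c, t.d
            row["chi2_raw"] = chi_square(t, yates=False)
            row["chi2_yates"] = chi_square(t, yates=True)
            if pt.chi2 is not None:
                dev = min(
                    abs(row["chi2_raw"] - pt.chi2),
                    abs(row["chi2_yates"] - pt.chi2),
                ) / pt.chi2
                row["chi2_rel_dev"] = dev
                row["chi2_ok"] = dev <= chi2_rtol
        out.append(row)
    return out


def _parse_opt_float(s: str) -> float | None:
    s = s.strip()
    return float(s) if s else None


def read_published_tuples(path: str | Path) -> list[PublishedTuple]:
    """Read a TSV of published tuples.

    Columns: pt, a, n_drug, ror, ci_low, ci_high, prr, chi2 (prr/chi2 may
    be blank). Rows with a blank report count ``a`` cannot form a
    :class:`PublishedTuple` and are skipped — the margin identity and the
    inversion both need the drug–event count.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if not row["a"].strip():
                continue
            out.append(
                PublishedTuple(
                    event_pt=row["pt"].strip(),
                    a=int(row["a"]),
                    n_drug=int(row["n_drug"]),
                    ror=float(row["ror"]),
                    ci_low=float(row["ci_low"]),
                    ci_high=float(row["ci_high"]),
                    prr=_parse_opt_float(row.get("prr", "")),
                    chi2=_parse_opt_float(row.get("chi2", "")),
                )
            )
    return out


def packaged_tuples_path() -> Path:
    """Path of the packaged published-signal fixture (ibuprofen/FAERS study)."""
    return Path(resources.files("pvsignals").joinpath("data/published_tuples.tsv"))
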