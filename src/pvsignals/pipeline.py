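"""End-to-end orchestration: simulate/load → dedup → describe → signals.

The stage order follows the standard spontaneous-report workflow: raw rows
are deduplicated to unique cases; descriptive tables are computed on the
target drug's primary-suspect cases (the denominator a published study
describes); disproportionality statistics are computed against the full
deduplicated background; finally, published tuples are re-checked with the
reconstruction module. Every emitted table has a deterministic row order,
and a JSON manifest records row counts plus the deduplication delta.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import descriptives as desc
from .reconstruction import consistency_report, packaged_tuples_path, read_published_tuples
from .reports import deduplicate, filter_primary_suspect, read_reports, write_reports
from .signals import ScreeningCriteria, detect_signals, lack_of_efficacy_table, summarize_classification
from .simulate import SimulationConfig, simulate_database

log = logging.getLogger("pvsignals")

SIGNAL_COLUMNS = (
    "Positive Signal",
    "Chi_Squared",
    "ROR",
    "95% CI Lower Bound",
    "95% CI Upper Bound",
    "PRR",
    "n",
    "Meets Screening Criteria",
)


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of ``input_path`` (a flat report extract) or ``simulation``
    (a :class:`~pvsignals.simulate.SimulationConfig`) must be given.
    """

    target_drug: str
    outdir: str | Path
    input_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    criteria: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    top_countries: int = 10
    route_other_threshold: float = 0.001
    published_tuples: str | Path | None = None
    seed: int | None = None

    def __post_init__(self):
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_path and simulation must be provided"
            )
        if self.seed is not None and self.simulation is not None:
            self.simulation.seed = self.seed


def write_frequency_table(ft, path: Path) -> int:
    rows = ft.to_records()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("category\tcount\tpercent\n")
        for r in rows:
            fh.write(f"{r['category']}\t{r['count']}\t{r['percent']}\n")
    return len(rows)


def write_signal_table(stats, path: Path) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SIGNAL_COLUMNS) + "\n")
        for s in stats:
            fh.write(
                f"{s.event_pt}\t{s.chi2:.2f}\t{s.ror:.2f}\t{s.ci_low:.2f}\t"
                f"{s.ci_high:.2f}\t{s.prr:.2f}\t{s.n_reports}\t"
                f"{'yes' if s.meets_evans else 'no'}\n"
            )
    return len(stats)


def write_consistency_table(rows, path: Path) -> int:
    cols = (
        "event_pt", "a", "n_drug", "ror", "prr_printed", "prr_implied",
        "prr_rel_dev", "prr_ok", "feasible", "c", "d", "chi2_printed",
        "chi2_raw", "chi2_yates", "chi2_rel_dev", "chi2_ok",
    )
    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return "yes" if v else "no"
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(fmt(r.get(c)) for c in cols) + "\n")
    return len(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and return the artifact manifest (also written
    to ``<outdir>/manifest.json``).

    An empty signal list is a valid outcome, not an error; the manifest
    always records the deduplication delta (raw rows, removed duplicates,
    unique cases).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"target_drug": cfg.target_drug, "tables": {}}

    log.info("stage=load")
    if cfg.input_path is not None:
        raw = read_reports(cfg.input_path)
        manifest["input"] = str(cfg.input_path)
    else:
        raw = simulate_database(cfg.simulation)
        manifest["input"] = f"simulated(seed={cfg.simulation.seed})"
        write_reports(raw, outdir / "simulated_reports.tsv")
        manifest["tables"]["simulated_reports"] = len(raw)

    log.info("stage=deduplicate")
    dedup = deduplicate(raw)
    manifest["raw_reports"] = len(raw)
    manifest["unique_cases"] = len(dedup)
    manifest["removed_duplicates"] = len(raw) - len(dedup)

    log.info("stage=filter_primary_suspect")
    target_set = filter_primary_suspect(dedup, cfg.target_drug)
    manifest["target_ps_cases"] = len(target_set)
    if not target_set.reports:
        log.warning("no primary-suspect reports for %r", cfg.target_drug)

    log.info("stage=descriptives")
    described = target_set if target_set.reports else dedup
    tables = {
        "yearly": desc.yearly_counts(described),
        "sex": desc.sex_distribution(described),
        "age": desc.age_distribution(described),
        "route": desc.route_distribution(described, cfg.route_other_threshold),
        "country": desc.country_distribution(described, cfg.top_countries),
    }
    outcome_table, unfavorable = desc.outcome_summary(described)
    tables["outcome"] = outcome_table
    manifest["unfavorable_cases"] = unfavorable
    for name, ft in tables.items():
        manifest["tables"][name] = write_frequency_table(ft, outdir / f"{name}.tsv")

    log.info("stage=signals")
    stats = detect_signals(dedup, cfg.target_drug, cfg.criteria)
    loe = lack_of_efficacy_table(dedup, cfg.target_drug, cfg.criteria)
    manifest["tables"]["signals"] = write_signal_table(stats, outdir / "signals.tsv")
    manifest["tables"]["lack_of_efficacy"] = write_signal_table(
        loe, outdir / "lack_of_efficacy.tsv"
    )
    if stats:
        pos, neg, pos_n, neg_n = summarize_classification(stats)
        manifest["classification"] = {
            "positive_signals": pos,
            "not_meeting_criteria": neg,  # a.k.a. "false signals"
            "positive_report_sum": pos_n,
            "negative_report_sum": neg_n,
        }

    log.info("stage=reconstruct")
    tuples_path = cfg.published_tuples or packaged_tuples_path()
    checks = consistency_report(read_published_tuples(tuples_path))
    manifest["tables"]["reconstruction"] = write_consistency_table(
        checks, outdir / "reconstruction.tsv"
    )

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
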