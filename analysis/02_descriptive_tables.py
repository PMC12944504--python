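"""Deduplicate the synthetic database and tabulate the descriptive
dimensions of the target drug's primary-suspect cases: yearly trend,
sex, age group, administration route, outcomes and country of origin.

Reads results/synthetic_reports.tsv (run 01 first); writes one TSV per
dimension under results/descriptives/ and prints the headline shares.
"""

from pathlib import Path

from pvsignals import (
    age_distribution,
    country_distribution,
    deduplicate,
    filter_primary_suspect,
    outcome_summary,
    read_reports,
    route_distribution,
    sex_distribution,
    yearly_counts,
)
from pvsignals.pipeline import write_frequency_table

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "descriptives"
OUT.mkdir(parents=True, exist_ok=True)

raw = read_reports(ROOT / "synthetic_reports.tsv")
dedup = deduplicate(raw)
target = filter_primary_suspect(dedup, "ibuprofen")
print(f"{len(raw)} raw rows -> {len(dedup)} unique cases; "
      f"{len(target)} with ibuprofen as primary suspect")

tables = {
    "yearly": yearly_counts(target),
    "sex": sex_distribution(target),
    "age": age_distribution(target),
    "route": route_distribution(target),
    "country": country_distribution(target),
}
outcome_table, unfavorable = outcome_summary(target)
tables["outcome"] = outcome_table

for name, ft in tables.items():
    write_frequency_table(ft, OUT / f"{name}.tsv")

print(f"sex shares (%): {tables['sex'].percents()}")
print(f"age-group shares (%): {tables['age'].percents()}")
print(f"cases with at least one unfavorable outcome: {unfavorable} "
      f"({100 * unfavorable / len(target):.1f}%)")
print(f"tables written under {OUT}")
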