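"""Draw the synthetic spontaneous-report database used by the later steps.

Emulates a FAERS-like extract: 20,000 unique cases plus follow-up
duplicate rows (raw/unique ratio matching the study's 79,632 -> 70,792
flowchart), ibuprofen as the target primary suspect in ~10% of cases,
and two planted associations — angioedema at a true reporting odds ratio
of 10 and acute kidney injury at 4 — against a 30-PT background.

Writes results/synthetic_reports.tsv and prints the ground truth.
"""

from pathlib import Path

from pvsignals import SimulationConfig, planted_truth, simulate_database, write_reports

OUT = Path(__file__).resolve().parent.parent / "results"

cfg = SimulationConfig(
    n_reports=20_000,
    planted_ror={"angioedema": 10.0, "acute kidney injury": 4.0},
    seed=2026,
)

rs = simulate_database(cfg)
OUT.mkdir(exist_ok=True)
write_reports(rs, OUT / "synthetic_reports.tsv")

truth = {pt: r for pt, r in planted_truth(cfg).items() if r != 1.0}
print(f"wrote {len(rs)} raw rows ({cfg.n_reports} unique cases) "
      f"to {OUT / 'synthetic_reports.tsv'}")
print(f"planted ground truth (true ROR): {truth}")
print("all other PTs have true ROR 1.0")
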