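# pvsignals

Disproportionality-based signal detection for spontaneous adverse-event
reports, built around the published FAERS analysis of ibuprofen: case
deduplication, descriptive epidemiology, ROR/PRR/χ² screening under Evans'
criteria, and algebraic re-verification of published signal tables — all
driven by a seeded synthetic report generator with known ground truth, so
every stage is testable without downloading FAERS.

## Who this is for

Pharmacovigilance analysts and methodologists who work with individual
case safety reports (ICSRs) from spontaneous reporting systems such as
FAERS, and who want a tested, reproducible implementation of the standard
signal-detection workflow rather than a spreadsheet.

## The statistics

For one target drug and one MedDRA preferred term (PT), reports are
cross-classified at the case level:

|                | event | no event |
|----------------|-------|----------|
| target drug PS | a     | b        |
| all other drugs| c     | d        |

* **ROR** = ad/bc, with the 95% Wald interval
  exp(ln ROR ± z·SE), SE = √(1/a + 1/b + 1/c + 1/d), z = 1.959964.
* **PRR** = [a/(a+b)] / [c/(c+d)].
* **χ²**: Pearson statistic over the four cells, Yates-corrected by
  default.
* **Evans' screening**: a pair is a *signal* when n ≥ 3, χ² > 4 and
  PRR > 2. A signal is a hypothesis for clinical review, not proof of
  causality.
* **Margin identity** (used to audit published tables): with
  b = n_drug − a and d/c = ROR·b/a,
  PRR = (a/n_drug)·(1 + ROR·b/a) exactly, independent of the background
  size — so a printed (a, ROR, PRR) triple can be checked without the
  hidden cells, and the Wald CI width can be inverted in closed form to
  recover (c, d) and recompute χ².

Zero cells are handled by the Haldane–Anscombe correction (0.5 added to
all four cells) for ROR/CI/PRR; χ² is always computed on raw cells.
Lack-of-efficacy reports (PT "drug ineffective") are tabulated separately
from ADR signals.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
database (20,000 unique cases plus follow-up duplicates, ibuprofen as
primary suspect in ~10%, angioedema planted at true ROR 10 and acute
kidney injury at 4):

```
python analysis/01_simulate_database.py
python analysis/02_descriptive_tables.py
python analysis/03_signal_detection.py
python analysis/04_published_consistency.py
```

Step 03 prints:

```
29 drug-event pairs screened: 2 meet Evans' criteria (1146 reports), 27 do not (4257 reports)
top 5 by chi-square:
PT      n       ROR     95% CI  PRR     chi2    Evans
angioedema      665     9.14    (8.16, 10.24)   6.31    1940.3  yes
acute kidney injury     481     4.25    (3.78, 4.78)    3.43    667.2   yes
product use in unapproved indication    215     0.87    (0.75, 1.01)    0.88    3.4     no
...
lack of efficacy: drug ineffective n=240 ROR=0.97 (tabulated separately from ADR signals)
```

Exactly the two planted associations are flagged; both 95% intervals
cover their true values (10 and 4); every null PT sits near ROR 1 and
fails screening; the lack-of-efficacy term never enters the ranking.

Step 04 audits the published ibuprofen signal table shipped with the
package: for all five fully printed tuples the margin-implied PRR matches
the printed PRR within 0.15%, and inverting the printed CI widths
recovers background cells whose χ² reproduces the printed values within
~2% (the urticaria CI is printed too coarsely to invert — the report says
so rather than guessing).

The same pipeline runs from a shell on any flat extract in the package's
TSV dialect:

```
pvsignals run --config my_sim.yaml --drug ibuprofen --outdir out/
pvsignals signals my_extract.tsv --drug ibuprofen --out signals.tsv
```

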