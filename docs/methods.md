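# Methods

## The workflow and its assumptions

Spontaneous reporting systems store one row per report *version*; a case
may be resubmitted with follow-up information under the same case
identifier and a larger version identifier. All analyses here operate on
the deduplicated set — the most recent version of each case — because
both descriptive denominators and contingency margins must count each
patient episode once. Version identifiers are compared numerically when
both parse as integers and lexicographically otherwise; ties are broken
by last occurrence in input order, and the surviving cases keep the order
of their first appearance, so deduplication is deterministic and
idempotent.

Disproportionality analysis assumes that, absent an association, the
share of reports mentioning a PT is the same for the target drug as for
the background. It inherits the well-known limitations of spontaneous
data: no exposure denominator, underreporting, reporting waves (Weber
effect, notoriety bias), and confounding by indication. The package
flags pairs, it does not adjudicate causality; and no multiplicity
correction is applied, matching standard practice for Evans-style
screening — a point repeated in the output metadata of the consistency
report rather than silently ignored.

## Statistics and numerical choices

* ROR = ad/bc; PRR = [a/(a+b)]/[c/(c+d)]; Wald CI on the log-odds scale
  with z = 1.959964 (the exact 97.5% normal quantile to 6 decimals; the
  difference from 1.96 is far below printed rounding).
* Zero cells: Haldane–Anscombe, 0.5 added to *all four* cells, applied
  only when at least one cell is zero, and only for ROR/CI/PRR. χ² is
  always computed on the raw cells with expected counts from the margins;
  degenerate margins raise an undefined-statistic error instead of
  returning 0 or infinity.
* χ² uses the clamped Yates form Σ(max(|O−E|−h,0))²/E with h = 0.5 by
  default. Whether a published χ² used Yates cannot be discriminated at
  the magnitudes involved (the difference is ≪ 1% there), so both
  settings are reported by the reconstruction module.
* Evans thresholds default to n ≥ 3, χ² > 4, PRR > 2 (strict
  inequalities on χ² and PRR). Published statements of the minimum count
  vary between ≥ 2 and > 2; the stricter reading matching Evans'
  original rule is the default and the threshold is configurable.
* Ranking sorts by χ² descending, ties by report count descending, then
  PT ascending — fully deterministic output tables.
* Percentages in descriptive tables are rounded half-up (via decimal
  arithmetic on the shortest float repr, so 2.675 → 2.68), one decimal
  for demographic summaries and two for route tables. Route categories
  partition reports: a multi-route report counts once under its
  highest-precedence named route (oral, transplacental, intravenous,
  then alphabetically), and named routes under 0.10% of the denominator
  fold into "Other". "Unspecified" (a recorded token) and "Unknown"
  (no route recorded) are kept distinct.
* Age groups default to <18, 18–64, ≥65 as half-open intervals, so age
  65 is elderly; bin edges are configurable and overlapping bins are
  rejected.

## Reconstruction of published tuples

Two exact identities make printed signal tables auditable without the
hidden background cells:

1. **Margin identity.** d/c = ROR·b/a by definition of the odds ratio,
   hence PRR = (a/n_drug)·(1 + ROR·b/a). This is an algebraic identity
   on any exact 2×2 table (property-tested to machine precision), so a
   printed PRR that disagrees with the printed (a, ROR) beyond rounding
   cannot come from any table with the stated drug margin. Checks use a
   1% relative tolerance, dominated by the 2-decimal rounding of printed
   RORs.
2. **CI inversion.** The Wald width fixes SE², so 1/c + 1/d =
   SE² − 1/a − 1/b; substituting d = ROR·b·c/a leaves a linear equation
   in 1/c, solved in closed form (no iterative solver, hence exact and
   deterministic). On unrounded inputs the inversion is the identity; on
   2-decimal printed CIs the recovered c can move by ±25% (measured by
   perturbing the bounds over their rounding interval), so recovered
   background sizes are reported as by-products, never headline numbers.
   χ² recomputed from the recovered cells is compared at 2% relative
   tolerance against the printed value under both Yates settings. A
   printed interval narrower than √(1/a + 1/b) admits no background at
   all; such tuples are reported infeasible with the deficit (this
   happens to one row of the packaged table, urticaria, whose CI is
   printed too coarsely), and one row (suicide attempt) reconstructs χ²
   at 2.2%, just outside the band — both verdicts are emitted as data,
   not hidden.

## The synthetic generator

The generator emulates the statistical structure the analysis relies on,
with defaults chosen to mirror the published study's dataset:

* **Scale and duplication.** `n_reports` unique cases; a fraction
  8,840/70,792 of them receive one follow-up row with identical payload
  and a larger version id, so the raw/unique ratio matches the study's
  79,632 → 70,792 flowchart and deduplication is exactly recoverable.
* **Events.** A 30-PT vocabulary (the scale of a top-30 ranking)
  compresses a real database's long PT tail; rates are balanced to give
  ≈2.4 expected events per report, the density of the study's data
  (176,356 events over 70,792 reports ≈ 2.49). Each PT enters a report
  by an independent Bernoulli draw whose *odds* are multiplied by the
  planted association strength when the primary suspect is the target
  drug — odds, not probability, so the report-level ROR estimable from
  the output converges exactly to the planted multiplier. A report that
  draws zero events receives one PT from its own conditional
  distribution (odds-adjusted for target reports); drawing the rescue
  from the background distribution instead would dilute planted
  associations toward the null, a bias large enough to matter at low
  event densities. With the default rates only ~8% of reports need the
  rescue and recovery is exact to sampling error (planted 10 →
  estimated 10.04 at n = 200,000).
* **Demographics and missingness.** Sex is missing with probability
  0.231 (F:M among recorded values 47.0:29.9), age with 0.454 (recorded
  ages split ≈20/57/23% across <18 / 18–64 / ≥65), route unspecified
  with 0.4219 and unknown with 0.2137, country with 0.0114 — the
  missingness proportions of the published dataset. Yearly weights rise
  to a 2021 peak then dip; the country pool is US-dominant with Western
  European contributors.
* **Determinism.** One numpy Generator stream with a documented draw
  order (suspect flags, background drugs, concomitants, years,
  countries, sex, age, routes, outcomes, events, rescues, duplicate
  selection); a seed fully determines the emitted TSV byte-for-byte.

What the generator does *not* model: reporter covariance, country-
specific reporting cultures, notoriety-bias dynamics, correlated event
syndromes, or a realistic long-tailed PT vocabulary. Passing tests
therefore demonstrate statistical correctness of the pipeline under a
clean reporting model, not robustness to the messiness of real FAERS
extracts.

## Problem sizes used by the test suite

The suite favours the smallest sizes at which each property is sharp:
oracle-equivalence runs 1,000 random sets of ≤84 reports; parameter
recovery uses one n = 200,000 database (planted ROR 10, the estimate
must land in [8, 12.5] and rank first by χ²); null coverage pools the
95% CIs of all 30 PTs over 200 seeds of n = 20,000 (6,000 intervals, so
the Monte-Carlo error of the coverage estimate, ~0.7%, is well inside
the 93–97% acceptance band — measured 94.25%); the flowchart-scale
deduplication check simulates 70,792 cases with 8,840 follow-ups.

## Known limitations

* The background is "all non-target reports in the provided set";
  whether a published background derives from the full database or a
  cleaned subset is generally unknowable from printed tables, and the
  CI inversion's recovered background size is correspondingly unstable.
* The "potential ADR" judgement of published tables encodes
  pharmacological knowledge; it is accepted as a user-supplied curated
  list and never computed.
* Bayesian disproportionality (IC, EBGM) is out of scope.
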