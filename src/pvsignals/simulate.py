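"""Seeded generator of spontaneous-report databases with known ground truth.

The generator emulates the statistical structure of a FAERS-style extract
for one target drug among many background drugs: per-event background
reporting rates, planted drug–event association strengths expressed as true
reporting odds ratios, follow-up duplicate rows sharing a case identifier,
demographic missingness, and a rise-then-dip yearly reporting trend.

Event generation is the part that matters for signal detection: each
preferred term (PT) is included in a report by an independent Bernoulli
draw whose *odds* — not probability — are multiplied by the planted
association strength when the report's primary suspect is the target drug.
Scaling odds rather than probabilities makes the report-level reporting
odds ratio estimable from the emitted database converge exactly to the
planted multiplier.

One numpy Generator stream drives everything, with a fixed draw order
(suspect flags, background drugs, concomitants, years, countries, sex,
age, routes, outcomes, events, zero-event rescues, duplicate selection),
so a seed fully determines the emitted dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .reports import NS, ReportSet, SafetyReport

# Background PT vocabulary with per-report background probabilities.
# Thirty PTs (the scale of a top-30 ranking) compressing a real database's
# long PT tail, so individual rates are higher than any single real PT;
# they are balanced to give ~2.4 expected events per report, the density
# spontaneous databases show (~2.5 PTs per case), which keeps zero-event
# draws rare. "drug ineffective" is the lack-of-efficacy term handled
# separately by the screening stage.
DEFAULT_EVENT_RATES: dict[str, float] = {
    "drug ineffective": 0.124,
    "nausea": 0.150,
    "vomiting": 0.140,
    "headache": 0.130,
    "product use in unapproved indication": 0.120,
    "rash": 0.120,
    "dizziness": 0.120,
    "fatigue": 0.120,
    "drug hypersensitivity": 0.100,
    "dyspnoea": 0.100,
    "off-label use": 0.090,
    "diarrhoea": 0.090,
    "pruritus": 0.090,
    "malaise": 0.090,
    "condition aggravated": 0.080,
    "abdominal pain upper": 0.080,
    "somnolence": 0.080,
    "toxicity to various agents": 0.070,
    "acute kidney injury": 0.070,
    "urticaria": 0.070,
    "incorrect dose administered": 0.060,
    "overdose": 0.060,
    "intentional overdose": 0.050,
    "abdominal discomfort": 0.050,
    "angioedema": 0.050,
    "gastrointestinal haemorrhage": 0.040,
    "anaphylactic reaction": 0.030,
    "gastric ulcer": 0.020,
    "melaena": 0.020,
    "toxic epidermal necrolysis": 0.010,
}

DEFAULT_BACKGROUND_DRUGS = (
    "paracetamol",
    "naproxen",
    "diclofenac",
    "acetylsalicylic acid",
    "omeprazole",
    "amoxicillin",
    "metformin",
    "atorvastatin",
    "lisinopril",
    "sertraline",
    "levothyroxine",
    "amlodipine",
    "prednisone",
    "gabapentin",
    "tramadol",
)

# Country pool: US-dominant with Western-European contributors, as in
# FAERS-style geographic distributions.
DEFAULT_COUNTRY_WEIGHTS: dict[str, float] = {
    "US": 0.622,
    "GB": 0.086,
    "DE": 0.054,
    "FR": 0.054,
    "IT": 0.032,
    "ES": 0.032,
    "CA": 0.020,
    "CN": 0.015,
    "PT": 0.011,
    "AU": 0.008,
    "NL": 0.007,
    "JP": 0.007,
    "BR": 0.007,
    "SE": 0.006,
    "PL": 0.006,
    "IN": 0.006,
    "MX": 0.005,
    "CH": 0.005,
    "BE": 0.005,
    "RO": 0.004,
    "TR": 0.004,
    "AR": 0.004,
}

# Named administration routes with per-report probabilities; the two
# missingness tokens are configured separately (route_unspecified /
# route_unknown in `missingness`) and absorb the remaining mass.
DEFAULT_ROUTE_WEIGHTS: dict[str, float] = {
    "oral": 0.3536,
    "transplacental": 0.0052,
    "intravenous": 0.0022,
    "topical": 0.0015,
    "rectal": 0.0009,
    "intramuscular": 0.0006,
    "nasal": 0.0004,
}

# Per-outcome report probabilities (a report may carry several codes).
DEFAULT_OUTCOME_RATES: dict[str, float] = {
    "DE": 0.043,
    "LT": 0.046,
    "HO": 0.243,
    "DS": 0.009,
    "CA": 0.003,
    "RI": 0.003,
    "OT": 0.050,
}

DEFAULT_MISSINGNESS: dict[str, float] = {
    "sex": 0.231,
    "age": 0.454,
    "route_unspecified": 0.4219,
    "route_unknown": 0.2137,
    "country": 0.0114,
}

# Yearly reporting weights: steady rise to a peak, then a slight dip —
# the qualitative shape of mature-drug reporting trends.
def _default_year_weights(lo: int, hi: int, peak: int = 2021) -> dict[int, float]:
    years = range(lo, hi + 1)
    w = {}
    for y in years:
        if y <= peak:
            w[y] = 1.0 + 4.0 * (y - lo) / max(peak - lo, 1)
        else:
            w[y] = 5.0 * (0.88 ** (y - peak))
    total = sum(w.values())
    return {y: v / total for y, v in w.items()}


class ConfigError(ValueError):
    """Invalid simulation configuration (raised before any sampling)."""


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic report database.

    ``n_reports`` counts unique cases; ``duplicate_fraction`` of them
    additionally receive one superseded follow-up row, so the raw emitted
    database holds ``n_reports + round(duplicate_fraction * n_reports)``
    rows.  ``planted_ror`` maps PTs to true reporting-odds multipliers for
    the target drug (1.0 = no association); PTs not listed default to 1.0.
    """

    n_reports: int = 20_000
    target_drug: str = "ibuprofen"
    p_target: float = 0.10
    background_event_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATES)
    )
    planted_ror: dict = field(default_factory=dict)
    events_per_report: float | None = None
    duplicate_fraction: float = 8840 / 70792
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    year_range: tuple = (2004, 2024)
    year_weights: dict | None = None
    outcome_rates: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_RATES))
    country_weights: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRY_WEIGHTS))
    route_weights: dict = field(default_factory=lambda: dict(DEFAULT_ROUTE_WEIGHTS))
    background_drugs: tuple = DEFAULT_BACKGROUND_DRUGS
    p_concomitant: float = 0.30
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigError("n_reports must be >= 1")
        probs = {
            "p_target": self.p_target,
            "duplicate_fraction": self.duplicate_fraction,
            "p_concomitant": self.p_concomitant,
            **{f"missingness[{k}]": v for k, v in self.missingness.items()},
            **{f"background_event_rates[{k}]": v
               for k, v in self.background_event_rates.items()},
            **{f"outcome_rates[{k}]": v for k, v in self.outcome_rates.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} = {p} outside [0, 1]")
        for pt, r in self.planted_ror.items():
            if r <= 0:
                raise ConfigError(f"planted_ror[{pt!r}] must be > 0")
            if pt not in self.background_event_rates:
                raise ConfigError(
                    f"planted_ror names unknown PT {pt!r} (not in "
                    "background_event_rates)"
                )
        lo, hi = self.year_range
        if lo > hi:
            raise ConfigError("year_range must be (lo, hi) with lo <= hi")
        route_mass = (
            sum(self.route_weights.values())
            + self.missingness["route_unspecified"]
            + self.missingness["route_unknown"]
        )
        if abs(route_mass - 1.0) > 1e-6:
            raise ConfigError(
                f"route weights + route missingness sum to {route_mass:.6f}, expected 1"
            )
        if self.events_per_report is not None and self.events_per_report < 1:
            raise ConfigError("events_per_report must be >= 1 when given")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "year_range" in d:
            d["year_range"] = tuple(d["year_range"])
        if "background_drugs" in d:
            d["background_drugs"] = tuple(d["background_drugs"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from YAML or JSON (YAML is a JSON superset)."""
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def planted_truth(cfg: SimulationConfig) -> dict[str, float]:
    """True reporting-odds multiplier per PT (1.0 where nothing was planted)."""
    return {
        pt: float(cfg.planted_ror.get(pt, 1.0))
        for pt in cfg.background_event_rates
    }


def _event_probabilities(cfg: SimulationConfig) -> np.ndarray:
    """Background inclusion probabilities, optionally rescaled so the
    expected number of events per report equals ``events_per_report``."""
    p = np.array(list(cfg.background_event_rates.values()), dtype=float)
    if cfg.events_per_report is not None:
        p = p * (cfg.events_per_report / p.sum())
        if (p >= 0.95).any():
            raise ConfigError(
                "events_per_report rescaling pushes a PT probability above 0.95"
            )
    return p


def simulate_database(cfg: SimulationConfig) -> ReportSet:
    """Draw one raw (non-deduplicated) report database.

    Deterministic for a fixed seed.  Follow-up duplicates share the
    case_id and full payload of their base case but carry a larger
    version_id, so deduplication is exactly recoverable.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports

    is_target = rng.random(n) < cfg.p_target
    bg_idx = rng.integers(0, len(cfg.background_drugs), size=n)
    has_conc = rng.random(n) < cfg.p_concomitant
    conc_idx = rng.integers(0, len(cfg.background_drugs), size=n)

    lo, hi = cfg.year_range
    yw = cfg.year_weights or _default_year_weights(lo, hi)
    years_pool = np.array(sorted(yw), dtype=int)
    yprob = np.array([yw[y] for y in years_pool], dtype=float)
    yprob = yprob / yprob.sum()
    years = rng.choice(years_pool, size=n, p=yprob)

    countries_pool = np.array(list(cfg.country_weights), dtype=object)
    cw = np.array(list(cfg.country_weights.values()), dtype=float)
    cw = cw / cw.sum()
    country = rng.choice(countries_pool, size=n, p=cw)
    country_missing = rng.random(n) < cfg.missingness["country"]

    # Sex: F/M split among recorded values mirrors the 47.0 : 29.9 ratio.
    u = rng.random(n)
    m_sex = cfg.missingness["sex"]
    f_share = 0.47 / (0.47 + 0.299)
    sex = np.where(u < m_sex, NS, np.where(u < m_sex + (1 - m_sex) * f_share, "F", "M"))

    age_missing = rng.random(n) < cfg.missingness["age"]
    # Age groups among recorded ages: children/adolescents, adults, elderly.
    grp = rng.choice(3, size=n, p=[0.2015, 0.5696, 0.2289])
    age_u = rng.random(n)
    age = np.select(
        [grp == 0, grp == 1, grp == 2],
        [age_u * 18.0, 18.0 + age_u * 47.0, 65.0 + age_u * 30.0],
    )
    age = np.floor(age)

    route_labels = list(cfg.route_weights) + ["unspecified", "unknown"]
    route_p = np.array(
        list(cfg.route_weights.values())
        + [cfg.missingness["route_unspecified"], cfg.missingness["route_unknown"]],
        dtype=float,
    )
    route_p = route_p / route_p.sum()
    route_idx = rng.choice(len(route_labels), size=n, p=route_p)

    out_codes = list(cfg.outcome_rates)
    out_p = np.array(list(cfg.outcome_rates.values()), dtype=float)
    out_draws = rng.random((n, len(out_codes))) < out_p

    pts = list(cfg.background_event_rates)
    p_bg = _event_probabilities(cfg)
    mult = np.array([cfg.planted_ror.get(pt, 1.0) for pt in pts], dtype=float)
    odds = p_bg / (1.0 - p_bg)
    p_target_drug = (odds * mult) / (1.0 + odds * mult)
    P = np.where(is_target[:, None], p_target_drug[None, :], p_bg[None, :])
    ev_draws = rng.random((n, len(pts))) < P
    # Zero-event rescue: one PT from the report's own conditional
    # distribution (odds-adjusted for target reports), so the rescue does
    # not pull planted associations toward the null.
    rescue_u = rng.random(n)
    cum_bg = np.cumsum(p_bg / p_bg.sum())
    cum_tg = np.cumsum(p_target_drug / p_target_drug.sum())
    rescue = np.where(
        is_target,
        np.searchsorted(cum_tg, rescue_u),
        np.searchsorted(cum_bg, rescue_u),
    ).clip(0, len(pts) - 1)

    n_dup = int(round(cfg.duplicate_fraction * n))
    dup_cases = np.sort(rng.choice(n, size=n_dup, replace=False)) if n_dup else np.array([], dtype=int)

    ev_lists = [
        [pts[j] for j in np.flatnonzero(ev_draws[i])] or [pts[rescue[i]]]
        for i in range(n)
    ]

    unknown_route = len(route_labels) - 1
    reports = []
    for i in range(n):
        drugs = []
        if is_target[i]:
            drugs.append((cfg.target_drug, "PS"))
        else:
            drugs.append((cfg.background_drugs[bg_idx[i]], "PS"))
        if has_conc[i]:
            conc = cfg.background_drugs[conc_idx[i]]
            if conc != drugs[0][0]:
                drugs.append((conc, "C"))
        reports.append(
            SafetyReport(
                case_id=f"C{i + 1:07d}",
                version_id=str(10 * (i + 1)),
                receipt_year=int(years[i]),
                country=NS if country_missing[i] else str(country[i]),
                sex=str(sex[i]),
                age_years=None if age_missing[i] else float(age[i]),
                routes=frozenset()
                if route_idx[i] == unknown_route
                else frozenset({route_labels[route_idx[i]]}),
                outcomes=frozenset(
                    c for k, c in enumerate(out_codes) if out_draws[i, k]
                ),
                drugs=tuple(drugs),
                events=frozenset(ev_lists[i]),
            )
        )

    for i in dup_cases:
        base = reports[i]
        reports.append(
            SafetyReport(
                case_id=base.case_id,
                version_id=str(10 * (i + 1) + 1),
                receipt_year=base.receipt_year,
                country=base.country,
                sex=base.sex,
                age_years=base.age_years,
                routes=base.routes,
                outcomes=base.outcomes,
                drugs=base.drugs,
                events=base.events,
            )
        )

    return ReportSet(reports=reports, deduplicated=False)
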