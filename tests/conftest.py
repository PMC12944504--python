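import pytest
from hypothesis import HealthCheck, settings

from pvsignals.reports import ReportSet, SafetyReport

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_report(case_id, version_id="1", year=2020, drugs=(("ibuprofen", "PS"),),
                events=("nausea",), **kw):
    return SafetyReport(
        case_id=case_id,
        version_id=version_id,
        receipt_year=year,
        drugs=tuple(drugs),
        events=frozenset(events),
        **kw,
    )


@pytest.fixture
def toy_set():
    """10 deduplicated reports: 4 with the target as primary suspect
    (2 mentioning pt_x), 6 background (1 mentioning pt_x) — the 2x2 for
    (target, pt_x) is (a,b,c,d) = (2,2,1,5) by hand count."""
    reports = [
        make_report("T1", events=("pt_x", "nausea")),
        make_report("T2", events=("pt_x",)),
        make_report("T3", events=("headache",)),
        make_report("T4", events=("rash", "nausea")),
        make_report("B1", drugs=(("naproxen", "PS"),), events=("pt_x",)),
        make_report("B2", drugs=(("naproxen", "PS"),), events=("nausea",)),
        make_report("B3", drugs=(("aspirin", "PS"),), events=("headache",)),
        make_report("B4", drugs=(("aspirin", "PS"), ("ibuprofen", "C")), events=("rash",)),
        make_report("B5", drugs=(("metformin", "PS"),), events=("nausea",)),
        make_report("B6", drugs=(("metformin", "PS"),), events=("fatigue",)),
    ]
    return ReportSet(reports=reports, deduplicated=True)
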