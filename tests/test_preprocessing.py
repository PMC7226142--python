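"""Inclusion funnel: seriousness, two-step dedup, aberrant chronology."""

import pytest

from pvsignal.dates import PartialDate
from pvsignal.faers_io import DrugRecord, EventRecord, Report
from pvsignal.preprocessing import (
    FunnelReport,
    deduplicate,
    filter_serious,
    remove_aberrant,
    run_funnel,
)


def _report(
    report_id,
    case_id=None,
    version=1,
    serious=True,
    terms=("Synthetic sign A",),
    onset=PartialDate(2018, 5, 1),
    age=60.0,
    sex="male",
    country="US",
    start=None,
):
    drugs = []
    if start is not None:
        drugs.append(DrugRecord("drug x", "primary suspect", therapy_start=start))
    return Report(
        report_id=report_id,
        case_id=case_id or report_id,
        version_seq=version,
        age_years=age,
        sex=sex,
        reporter_type="unknown",
        country=country,
        reporting_year=2018,
        outcome=frozenset({"hospitalization"}) if serious else frozenset(),
        drugs=drugs,
        events=[EventRecord(t, onset) for t in terms],
    )


def test_filter_serious_counts():
    reports = [_report(f"r{i}", serious=i >= 3) for i in range(10)]
    kept, removed = filter_serious(reports)
    assert len(kept) == 7 and removed == 3
    # identity on the already-serious subset
    kept2, removed2 = filter_serious(kept)
    assert kept2 == kept and removed2 == 0


def test_dedup_keeps_last_version_per_case():
    versions = [_report(f"p{v}", case_id="c1", version=v) for v in (1, 2, 3)]
    kept, removed = deduplicate(versions)
    assert [r.report_id for r in kept] == ["p3"] and removed == 2


def test_dedup_collapses_identical_key_across_cases():
    a = _report("p1", case_id="c1")
    b = _report("p2", case_id="c2")  # same event/date/age/sex/country
    kept, removed = deduplicate([a, b])
    assert removed == 1
    assert kept[0].report_id == "p1"  # deterministic: smallest report_id


def test_dedup_key_mismatch_retains_both():
    a = _report("p1", case_id="c1", country="US")
    b = _report("p2", case_id="c2", country="FR")
    assert deduplicate([a, b])[1] == 0
    c = _report("p3", case_id="c3", onset=None)
    d = _report("p4", case_id="c4", onset=None)
    # missing dates compare equal only to missing: these two DO collide
    assert deduplicate([c, d])[1] == 1


def test_aberrant_rules():
    aberrant = _report("p1", start=PartialDate(2018, 6, 1), onset=PartialDate(2018, 5, 1))
    same_day = _report("p2", start=PartialDate(2018, 5, 1), onset=PartialDate(2018, 5, 1))
    missing_start = _report("p3", start=None, onset=PartialDate(2018, 5, 1))
    partial_start = _report("p4", start=PartialDate(2018, 6), onset=PartialDate(2018, 5, 1))
    kept, removed = remove_aberrant([aberrant, same_day, missing_start, partial_start])
    assert removed == 1
    assert {r.report_id for r in kept} == {"p2", "p3", "p4"}


def test_aberrant_requires_all_dated_drugs_after_onset():
    r = _report("p1", start=PartialDate(2018, 6, 1), onset=PartialDate(2018, 5, 1))
    r.drugs.append(
        DrugRecord("drug y", "concomitant", therapy_start=PartialDate(2018, 4, 1))
    )
    # one dated drug starts before the event: chronology is plausible
    assert remove_aberrant([r])[1] == 0


def test_funnel_identity_and_idempotence():
    reports = [
        _report("p1", serious=False),
        _report("p2", case_id="c2", version=1),
        _report("p3", case_id="c2", version=2),
        _report("p4", case_id="c4", onset=PartialDate(2018, 5, 2)),
        _report("p5", case_id="c5", onset=PartialDate(2018, 5, 3),
                start=PartialDate(2018, 6, 1)),
    ]
    # make p5 aberrant: onset before its start
    retained, funnel = run_funnel(reports)
    assert funnel.n_input == 5
    assert funnel.n_nonserious_removed == 1
    assert funnel.n_duplicates_removed == 1
    assert funnel.n_aberrant_removed == 1
    assert funnel.n_retained == len(retained) == 2
    # idempotence: a second pass removes nothing
    retained2, funnel2 = run_funnel(retained)
    assert retained2 == retained and funnel2.n_retained == funnel2.n_input


def test_funnel_report_identity_enforced():
    with pytest.raises(ValueError):
        FunnelReport(n_input=10, n_nonserious_removed=1, n_duplicates_removed=1,
                     n_aberrant_removed=1, n_retained=8)
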