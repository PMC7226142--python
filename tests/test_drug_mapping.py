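"""Drug-name normalization cascade and exposure flagging."""

import itertools

import pytest

from pvsignal.drug_mapping import (
    STUDY_TKIS,
    ExposureFlags,
    flag_exposures,
    mapping_coverage,
    normalize_name,
    resolve_components,
)
from pvsignal.faers_io import DrugRecord, Report


def _report(drug_names_roles, report_id="r1"):
    return Report(
        report_id=report_id,
        case_id=report_id,
        version_seq=1,
        age_years=None,
        sex="unknown",
        reporter_type="unknown",
        country="unknown",
        reporting_year=None,
        outcome=frozenset({"other serious"}),
        drugs=[DrugRecord(verbatim_name=n, role=r) for n, r in drug_names_roles],
    )


@pytest.mark.parametrize(
    "verbatim, expected",
    [
        ("GLEEVEC 400MG", "imatinib"),
        ("Tasigna", "nilotinib"),
        ("imatinib", "imatinib"),
        ("SPRYCEL 100 MG TABLET", "dasatinib"),
        ("VITAMIN C", None),
        ("", None),
    ],
)
def test_normalization_cascade(tiny_archive, verbatim, expected):
    assert normalize_name(verbatim, tiny_archive) == expected


def _levenshtein(a: str, b: str) -> int:
    # classic DP, the brute-force oracle for the bounded rescue
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def test_edit_distance_rescue_matches_brute_force(tiny_archive):
    """A unique distance-1 neighbour resolves; ambiguous/absent do not."""
    for token in ["imatnib", "nilotinb", "dasatinibb", "bosutnib", "xyzzyplugh"]:
        hits = {
            inn
            for key, inn in tiny_archive.entries.items()
            if _levenshtein(token, key) <= 1
        }
        expected = next(iter(hits)) if len(hits) == 1 else None
        got = normalize_name(token, tiny_archive, edit_distance_rescue=True)
        assert got == expected, token


def test_rescue_is_opt_in_and_length_gated(tiny_archive):
    assert normalize_name("imatnib", tiny_archive) is None
    # short tokens are never rescued even when enabled
    assert normalize_name("taxl", tiny_archive, edit_distance_rescue=True) is None


def test_normalization_is_idempotent_on_inns(tiny_archive):
    for inn in tiny_archive.atc_index:
        assert normalize_name(inn, tiny_archive) == inn


def test_multi_ingredient_names_resolve_per_component(tiny_archive):
    assert resolve_components("imatinib + paclitaxel", tiny_archive) == {
        "imatinib",
        "paclitaxel",
    }
    assert resolve_components("imatinib + unknownium", tiny_archive) == {"imatinib"}


def test_mapping_coverage_fraction(tiny_archive):
    reports = [
        _report([("Gleevec", "primary suspect")] * 9 + [("mysteron", "concomitant")])
    ]
    frac, unresolved = mapping_coverage(reports, tiny_archive)
    assert frac == pytest.approx(0.9)
    assert unresolved[0][0] == "mysteron"
    assert mapping_coverage([], tiny_archive) == (None, [])


def test_all_resolved_coverage_is_one(tiny_archive):
    reports = [_report([("Tasigna", "primary suspect"), ("Taxol", "concomitant")])]
    assert mapping_coverage(reports, tiny_archive)[0] == 1.0


def test_exposure_flags_cover_all_roles(tiny_archive):
    r = _report([("Tasigna", "concomitant")])
    flags = flag_exposures(r, tiny_archive)
    assert flags.is_anticancer and flags.tki_set == {"nilotinib"}

    r = _report([("Dolorex", "primary suspect")])
    flags = flag_exposures(r, tiny_archive)
    assert not flags.is_anticancer and flags.tki_set == frozenset()

    r = _report([("Gleevec", "primary suspect"), ("Iclusig", "secondary suspect")])
    assert flag_exposures(r, tiny_archive).tki_set == {"imatinib", "ponatinib"}


def test_exposure_flags_order_invariant(tiny_archive):
    drugs = [("Taxol", "concomitant"), ("Tasigna", "primary suspect"), ("Dolorex", "concomitant")]
    flags = {
        flag_exposures(_report(list(perm)), tiny_archive)
        for perm in itertools.permutations(drugs)
    }
    assert len(flags) == 1


def test_tki_implies_anticancer_invariant():
    with pytest.raises(ValueError):
        ExposureFlags(is_anticancer=False, tki_set=frozenset({"imatinib"}))


def test_synthetic_flags_match_ground_truth():
    """With misspellings off, pipeline flags equal the generator's plan."""
    from pvsignal import synthetic
    from pvsignal.faers_io import assemble_reports

    cfg = synthetic.default_scenario(n_reports=300, seed=5, misspell_rate=0.0)
    tables, truth = synthetic.generate(cfg)
    archive = synthetic.build_archive(cfg)
    reports = {r.report_id: r for r in assemble_reports(tables)}
    for _, row in truth.cohort.iterrows():
        flags = flag_exposures(reports[row["report_id"]], archive)
        assert flags.is_anticancer
        expected = frozenset({row["drug"]}) if row["is_tki"] else frozenset()
        assert flags.tki_set == expected
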