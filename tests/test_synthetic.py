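"""Generator determinism, injected-artefact bookkeeping, preset margins."""

import dataclasses

import numpy as np
import pytest

from pvsignal import synthetic
from pvsignal.disproportionality import TKI_CLASS, build_table
from pvsignal.drug_mapping import mapping_coverage
from pvsignal.pipeline import build_screen_inputs, prepare_reports


def test_determinism_byte_identical(tmp_path):
    cfg = synthetic.default_scenario(n_reports=200, seed=9)
    synthetic.generate(cfg, out_dir=tmp_path / "a")
    synthetic.generate(cfg, out_dir=tmp_path / "b")
    for name in ("demo", "drug", "reac", "outc", "indi", "ther"):
        assert (tmp_path / "a" / f"{name}.txt").read_bytes() == (
            tmp_path / "b" / f"{name}.txt"
        ).read_bytes()


def test_validation_rejects_bad_configs():
    cfg = synthetic.default_scenario(n_reports=10)
    with pytest.raises(ValueError, match="dup_rate"):
        dataclasses.replace(cfg, dup_rate=1.5).validate()
    bad_menu = cfg.drug_menu[:-1]
    with pytest.raises(ValueError, match="shares"):
        dataclasses.replace(cfg, drug_menu=bad_menu).validate()
    with pytest.raises(ValueError, match="positive"):
        dataclasses.replace(cfg, true_or={("a", "b"): -1}).validate()


def test_clean_config_removes_only_nonserious():
    cfg = synthetic.default_scenario(
        n_reports=400, seed=2, dup_rate=0.0, followup_rate=0.0, aberrant_rate=0.0
    )
    tables, truth = synthetic.generate(cfg)
    archive = synthetic.build_archive(cfg)
    _, funnel = prepare_reports(tables, archive)
    assert funnel.n_nonserious_removed == truth.n_nonserious
    assert funnel.n_duplicates_removed == 0
    assert funnel.n_aberrant_removed == 0
    assert funnel.n_retained == truth.n_retained


def test_ground_truth_tables_match_pipeline_exactly():
    cfg = synthetic.default_scenario(
        n_reports=600, seed=3, dup_rate=0.0, followup_rate=0.0,
        aberrant_rate=0.0, misspell_rate=0.0,
    )
    tables, truth = synthetic.generate(cfg)
    archive = synthetic.build_archive(cfg)
    catalogue = synthetic.build_catalogue(cfg)
    retained, _ = prepare_reports(tables, archive)
    inputs = build_screen_inputs(retained, archive, catalogue)
    for smq in ("cardiac failure", "embolic and thrombotic events"):
        for drug in ("nilotinib", "dasatinib", TKI_CLASS):
            assert build_table(inputs.labels[smq], inputs.exposures, drug) == truth.contingency(drug, smq)


def test_injected_artifact_counts_match_funnel(small_tables, archive):
    tables, truth = small_tables
    _, funnel = prepare_reports(tables, archive)
    assert funnel.n_input == truth.n_input
    assert funnel.n_nonserious_removed == truth.n_nonserious
    assert funnel.n_duplicates_removed == truth.n_duplicates
    assert funnel.n_aberrant_removed == truth.n_aberrant
    assert funnel.n_retained == truth.n_retained


def test_mapping_coverage_matches_design(small_tables, archive):
    from pvsignal.faers_io import assemble_reports

    tables, truth = small_tables
    reports = assemble_reports(tables)
    frac, _ = mapping_coverage(reports, archive, edit_distance_rescue=True)
    assert frac == pytest.approx(truth.design_coverage, abs=0.02)


def test_reference_preset_expected_margins_are_exact():
    """The preset's design arithmetic reproduces the target case mix."""
    cfg = synthetic.reference_cohort_preset()
    tki = [d for d in cfg.drug_menu if d.is_tki]
    expected_cases = {d.inn: d.share * d.case_prob for d in tki}
    total = sum(expected_cases.values())
    assert expected_cases["nilotinib"] / total == pytest.approx(2319 / 3930, abs=1e-12)
    assert cfg.sex_probs_tki["male"] == pytest.approx(0.529)


def test_reference_preset_realized_margins():
    """Realized case-mix margins land within 2 points of the design.

    TKI cases are only ~0.5% of reports, so ten 100k cohorts are pooled
    to put the Monte-Carlo error well inside the tolerance.
    """
    n_nilotinib = n_male = n_tki_cases = n_cases = 0
    for rep in range(10):
        cfg = synthetic.reference_cohort_preset(n_reports=100000, seed=17 + rep)
        cohort = synthetic.simulate_cohort(cfg)
        case_cols = [c for c in cohort.columns if c.startswith("smqcase_")]
        any_case = cohort[case_cols].any(axis=1)
        tki_cases = cohort[cohort["is_tki"] & any_case]
        n_nilotinib += int((tki_cases["drug"] == "nilotinib").sum())
        n_male += int((tki_cases["sex"] == "male").sum())
        n_tki_cases += len(tki_cases)
        n_cases += int(any_case.sum())
    assert n_nilotinib / n_tki_cases == pytest.approx(0.590, abs=0.02)
    assert n_male / n_tki_cases == pytest.approx(0.529, abs=0.02)
    assert n_tki_cases / n_cases == pytest.approx(0.061, abs=0.02)


def test_cohort_exposure_and_case_rates_follow_config():
    cfg = synthetic.recovery_scenario(n_reports=30000, seed=8)
    cohort = synthetic.simulate_cohort(cfg)
    smq = "torsade de pointes/QT prolongation"
    exposed = cohort["drug"] == "nilotinib"
    p_case_comp = cohort.loc[~cohort["is_tki"], f"smqcase_{smq}"].mean()
    p_case_exp = cohort.loc[exposed, f"smqcase_{smq}"].mean()
    # planted effect shows up as a strongly elevated raw case rate
    assert p_case_exp > 4 * p_case_comp
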