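"""Reference counts for the worked example.

These are the printed descriptive counts of a published case/non-case
analysis of cardiovascular adverse-event reports for the five CML
tyrosine-kinase inhibitors in FAERS (serious reports, 2008-2018): the
report-inclusion funnel totals, the case/non-case margins per drug and
per cardiovascular SMQ, and the case-characteristic strata.  They serve
as a worked example for the descriptive-summary and crude-ROR machinery
— counts only; no record-level data is reproduced here.
"""

from __future__ import annotations

from typing import Dict

__all__ = ["cml_tki_reference_counts"]


def cml_tki_reference_counts() -> Dict[str, Dict]:
    """Printed counts of the reference CML-TKI cardiovascular cohort."""
    return {
        "totals": {
            "all_reports": 20204802,
            "anticancer_reports": 1306242,
            "nonserious_removed": 163354,
            "duplicates_removed": 357517,
            "aberrant_removed": 68208,
            "retained": 717163,
            "cv_cases": 64232,
            "tki_cv_cases": 3930,
            "tki_reports": 24373,
            "tki_noncases": 20443,
        },
        # cases of cardiovascular toxicity among TKI reports, by drug
        "tki_cases_by_drug": {
            "nilotinib": 2319,
            "dasatinib": 835,
            "ponatinib": 565,
            "imatinib": 173,
            "bosutinib": 38,
        },
        "tki_noncases_by_drug": {
            "nilotinib": 9014,
            "dasatinib": 6382,
            "ponatinib": 2536,
            "imatinib": 2291,
            "bosutinib": 220,
        },
        "tki_case_sex": {"female": 1423, "male": 2079, "unknown": 428},
        "tki_case_age_class": {
            "<=25": 41,
            "26-50": 436,
            "51-75": 1729,
            ">=76": 490,
            "unknown": 1234,
        },
        "tki_case_reporter": {
            "health professional": 2877,
            "nonhealth professional": 951,
            "unknown": 102,
        },
        "tki_case_country": {
            "US": 1263,
            "JP": 418,
            "DE": 293,
            "FR": 275,
            "other": 1505,
            "unknown": 176,
        },
        "tki_case_outcome": {
            "death": 396,
            "life-threatening": 171,
            "hospitalization": 1375,
            "disability": 63,
            "required intervention": 2,
            "congenital anomaly": 1,
            "other serious": 1922,
        },
        "tki_case_indication": {
            "chronic myeloid leukemia": 2678,
            "acute myeloid leukemia": 16,
            "acute lymphocytic leukemia": 159,
            "myeloid leukemia": 22,
            "gastrointestinal stromal tumour": 52,
            "hypertension": 19,
            "other indication": 341,
            "unknown": 643,
        },
        "tki_case_year": {
            "2008": 120,
            "2009": 106,
            "2010": 163,
            "2011": 209,
            "2012": 284,
            "2013": 422,
            "2014": 546,
            "2015": 415,
            "2016": 481,
            "2017": 501,
            "2018": 679,
            "unknown": 4,
        },
        # cases per cardiovascular SMQ: TKI column and comparator column
        "smq_cases_tki": {
            "cardiac arrhythmias": 126,
            "cardiac failure": 669,
            "cardiomyopathy": 78,
            "embolic and thrombotic events": 1049,
            "hypertension": 306,
            "ischaemic heart disease": 1306,
            "pulmonary hypertension": 127,
            "torsade de pointes/QT prolongation": 269,
        },
        "smq_cases_comparator": {
            "cardiac arrhythmias": 1982,
            "cardiac failure": 8402,
            "cardiomyopathy": 3238,
            "embolic and thrombotic events": 27911,
            "hypertension": 8236,
            "ischaemic heart disease": 8833,
            "pulmonary hypertension": 854,
            "torsade de pointes/QT prolongation": 846,
        },
    }
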