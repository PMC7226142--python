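"""End-to-end orchestration: raw tables -> funnel -> screen inputs.

Each step delegates to its module; this is the path the CLI and the
integration tests drive.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .disproportionality import ScreenInputs
from .drug_mapping import DrugArchive, annotate_reports, flag_exposures
from .faers_io import RawTableSet, Report, assemble_reports
from .preprocessing import FunnelReport, run_funnel
from .smq import SMQCatalogue, classify_reports

__all__ = ["filter_anticancer", "build_screen_inputs", "prepare_reports"]


def filter_anticancer(
    reports: Sequence[Report],
    archive: DrugArchive,
    edit_distance_rescue: bool = True,
) -> Tuple[List[Report], int]:
    """Restrict to reports carrying >=1 anticancer (ATC L01) drug, any role."""
    kept = [
        r
        for r in reports
        if flag_exposures(r, archive, edit_distance_rescue).is_anticancer
    ]
    return kept, len(reports) - len(kept)


def prepare_reports(
    tables: RawTableSet,
    archive: DrugArchive,
    edit_distance_rescue: bool = True,
) -> Tuple[List[Report], FunnelReport]:
    """Assemble, restrict to anticancer exposure, and run the funnel."""
    reports = assemble_reports(tables)
    annotate_reports(reports, archive, edit_distance_rescue)
    anticancer, _ = filter_anticancer(reports, archive, edit_distance_rescue)
    return run_funnel(anticancer)


def build_screen_inputs(
    reports: Sequence[Report],
    archive: DrugArchive,
    catalogue: SMQCatalogue,
    scope: str = "narrow",
    edit_distance_rescue: bool = True,
) -> ScreenInputs:
    """Labels, exposures and covariates for the retained report set."""
    labels = classify_reports(reports, catalogue, scope)
    index = labels.index
    exposures = pd.Series(
        [flag_exposures(r, archive, edit_distance_rescue).tki_set for r in reports],
        index=index,
    )
    covariates = pd.DataFrame(
        {"age_class": [r.age_class for r in reports], "sex": [r.sex for r in reports]},
        index=index,
    )
    return ScreenInputs(labels=labels, exposures=exposures, covariates=covariates)
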