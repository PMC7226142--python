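"""The report-inclusion funnel: seriousness, deduplication, aberrant dates.

Spontaneous-report databases accumulate follow-up versions of the same
case and outright duplicates submitted through different channels; a
minority of reports also carry impossible chronology (therapy starting
after the event).  The funnel applied here is order-fixed:

1. keep serious reports only;
2. deduplicate — first keep the last version per case, then collapse
   reports identical on (event term set, event date, age, sex, country);
3. drop aberrant reports (every dated drug starts strictly after the
   event onset).

Each stage is idempotent, and the counts removed are returned in a
:class:`FunnelReport` whose arithmetic identity always holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .faers_io import Report

__all__ = ["FunnelReport", "filter_serious", "deduplicate", "remove_aberrant", "run_funnel"]


@dataclass(frozen=True)
class FunnelReport:
    """Bookkeeping for one funnel run; the identity below is enforced."""

    n_input: int
    n_nonserious_removed: int
    n_duplicates_removed: int
    n_aberrant_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        expected = (
            self.n_input
            - self.n_nonserious_removed
            - self.n_duplicates_removed
            - self.n_aberrant_removed
        )
        if self.n_retained != expected:
            raise ValueError(
                f"funnel identity violated: retained {self.n_retained} != {expected}"
            )

    def as_dict(self) -> Dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_nonserious_removed": self.n_nonserious_removed,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_aberrant_removed": self.n_aberrant_removed,
            "n_retained": self.n_retained,
        }


def filter_serious(reports: Sequence[Report]) -> Tuple[List[Report], int]:
    """Retain reports with at least one seriousness outcome."""
    kept = [r for r in reports if r.serious]
    return kept, len(reports) - len(kept)


def _duplicate_key(report: Report) -> tuple:
    """Five-field duplicate key: event terms, event date, age, sex, country.

    The term set is the sorted set of case-folded preferred terms; the
    event date is the earliest onset in the report (missing dates match
    only missing).
    """
    terms = tuple(sorted({e.preferred_term.casefold().strip() for e in report.events}))
    onset = report.earliest_onset()
    return (
        terms,
        onset.isoformat() if onset is not None else None,
        report.age_years,
        report.sex,
        report.country,
    )


def deduplicate(reports: Sequence[Report]) -> Tuple[List[Report], int]:
    """Two-step deduplication.

    Step 1 keeps, within each case, the report with the highest version
    number (the latest follow-up).  Step 2 groups the survivors on the
    five-field duplicate key and keeps one representative per group —
    the lexicographically smallest report_id, a deterministic tie-break.
    """
    latest: Dict[str, Report] = {}
    for r in reports:
        cur = latest.get(r.case_id)
        # higher version wins; equal versions keep the smaller report_id
        if (
            cur is None
            or r.version_seq > cur.version_seq
            or (r.version_seq == cur.version_seq and r.report_id < cur.report_id)
        ):
            latest[r.case_id] = r
    survivors = list(latest.values())

    by_key: Dict[tuple, Report] = {}
    for r in survivors:
        key = _duplicate_key(r)
        cur = by_key.get(key)
        if cur is None or r.report_id < cur.report_id:
            by_key[key] = r
    kept = sorted(by_key.values(), key=lambda r: r.report_id)
    return kept, len(reports) - len(kept)


def _is_aberrant(report: Report) -> bool:
    onset = report.earliest_onset(full_precision_only=True)
    if onset is None:
        return False
    starts = [
        d.therapy_start
        for d in report.drugs
        if d.therapy_start is not None and d.therapy_start.is_full
    ]
    if not starts:
        return False
    # strictly after: a start on the event day is chronologically possible
    return all(s.to_date() > onset.to_date() for s in starts)


def remove_aberrant(reports: Sequence[Report]) -> Tuple[List[Report], int]:
    """Drop reports whose every dated drug starts strictly after the event.

    Reports with missing or partial dates on either side are retained:
    partial precision is insufficient evidence of impossible chronology.
    """
    kept = [r for r in reports if not _is_aberrant(r)]
    return kept, len(reports) - len(kept)


def run_funnel(reports: Sequence[Report]) -> Tuple[List[Report], FunnelReport]:
    """Apply the full funnel (serious -> dedup -> aberrant) and account for it."""
    n_input = len(reports)
    serious, n_nonserious = filter_serious(reports)
    deduped, n_dup = deduplicate(serious)
    retained, n_aberrant = remove_aberrant(deduped)
    return retained, FunnelReport(
        n_input=n_input,
        n_nonserious_removed=n_nonserious,
        n_duplicates_removed=n_dup,
        n_aberrant_removed=n_aberrant,
        n_retained=len(retained),
    )
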