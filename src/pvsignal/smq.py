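"""Standardised MedDRA Query (SMQ) catalogues and case classification.

An SMQ is a curated set of MedDRA Preferred Terms describing one medical
condition; the "narrow" scope lists terms specific for the condition,
the "broad" scope adds sensitive ones.  The case/non-case design labels
a report a *case* for an SMQ when at least one of its events matches the
query (narrow scope by default — better positive predictive value at
equivalent sensitivity); every other retained serious report is a
non-case, including reports matching other cardiovascular queries.

MedDRA itself is licensed, so term lists are always user-supplied
configuration; nothing here depends on real dictionary content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .faers_io import Report

__all__ = [
    "STUDY_SMQS",
    "SMQDefinition",
    "SMQCatalogue",
    "CaseLabel",
    "load_smq_catalogue",
    "classify",
    "classify_reports",
]

#: the eight cardiovascular queries screened in the CML TKI analysis
STUDY_SMQS = (
    "cardiac failure",
    "cardiomyopathy",
    "hypertension",
    "pulmonary hypertension",
    "ischaemic heart disease",
    "torsade de pointes/QT prolongation",
    "cardiac arrhythmias",
    "embolic and thrombotic events",
)

_WS_RE = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Case-fold and collapse whitespace; PT matching is otherwise exact."""
    return _WS_RE.sub(" ", str(term).casefold()).strip()


class SMQFormatError(ValueError):
    """A term-list file violates the catalogue format."""


@dataclass(frozen=True)
class SMQDefinition:
    """One query: a name plus scoped preferred terms."""

    name: str
    terms: Mapping[str, str]  # normalized term -> "narrow" | "broad"

    @property
    def narrow_terms(self) -> FrozenSet[str]:
        return frozenset(t for t, s in self.terms.items() if s == "narrow")

    @property
    def all_terms(self) -> FrozenSet[str]:
        return frozenset(self.terms)

    def term_set(self, scope: str) -> FrozenSet[str]:
        if scope == "narrow":
            return self.narrow_terms
        if scope == "broad":
            return self.all_terms
        raise ValueError(f"scope must be 'narrow' or 'broad', got {scope!r}")


@dataclass
class SMQCatalogue:
    definitions: Dict[str, SMQDefinition] = field(default_factory=dict)

    def __getitem__(self, name: str) -> SMQDefinition:
        return self.definitions[name]

    def __iter__(self):
        return iter(self.definitions.values())

    def __len__(self) -> int:
        return len(self.definitions)

    @property
    def names(self) -> List[str]:
        return list(self.definitions)


@dataclass(frozen=True)
class CaseLabel:
    report_id: str
    smq_name: str
    is_case: bool


def load_smq_catalogue(
    path: str | Path,
    required: Optional[Sequence[str]] = STUDY_SMQS,
    sep: str = "\t",
) -> SMQCatalogue:
    """Load a delimited (smq_name, preferred_term, scope) term-list file.

    A term listed for the same SMQ under both scopes is a format error;
    with ``required`` set (default: the eight study queries) any missing
    query raises, naming it.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    expected = ["smq_name", "preferred_term", "scope"]
    if list(df.columns) != expected:
        raise SMQFormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    terms: Dict[str, Dict[str, str]] = {}
    for _, row in df.iterrows():
        name = str(row["smq_name"]).strip()
        term = normalize_term(row["preferred_term"])
        scope = str(row["scope"]).strip().lower()
        if scope not in {"narrow", "broad"}:
            raise SMQFormatError(f"{path}: invalid scope {row['scope']!r} for term {term!r}")
        if not term:
            raise SMQFormatError(f"{path}: empty preferred term under SMQ {name!r}")
        bucket = terms.setdefault(name, {})
        if term in bucket and bucket[term] != scope:
            raise SMQFormatError(
                f"{path}: term {term!r} listed with conflicting scopes under SMQ {name!r}"
            )
        bucket[term] = scope
    catalogue = SMQCatalogue(
        {name: SMQDefinition(name=name, terms=bucket) for name, bucket in terms.items()}
    )
    if required:
        missing = [name for name in required if name not in catalogue.definitions]
        if missing:
            raise SMQFormatError(f"{path}: catalogue is missing required SMQs: {missing}")
    return catalogue


def write_smq_catalogue(catalogue: SMQCatalogue, path: str | Path, sep: str = "\t") -> Path:
    rows = [
        {"smq_name": d.name, "preferred_term": t, "scope": s}
        for d in catalogue
        for t, s in sorted(d.terms.items())
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["smq_name", "preferred_term", "scope"]).to_csv(
        path, sep=sep, index=False
    )
    return path


def classify(report: Report, smq: SMQDefinition, scope: str = "narrow") -> CaseLabel:
    """Label one report as case/non-case for one SMQ.

    A case holds at least one event whose preferred term is in the
    query's term set at the requested scope; everything else — including
    reports matching *other* queries — is a non-case for this SMQ.
    """
    term_set = smq.term_set(scope)
    is_case = any(normalize_term(e.preferred_term) in term_set for e in report.events)
    return CaseLabel(report_id=report.report_id, smq_name=smq.name, is_case=is_case)


def classify_reports(
    reports: Sequence[Report],
    catalogue: SMQCatalogue,
    scope: str = "narrow",
) -> pd.DataFrame:
    """Case labels for every report x SMQ; boolean frame indexed by report_id."""
    data = {
        smq.name: [classify(r, smq, scope).is_case for r in reports] for smq in catalogue
    }
    return pd.DataFrame(data, index=pd.Index([r.report_id for r in reports], name="report_id"))
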