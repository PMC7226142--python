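"""Free-text drug-name normalization to INN and ATC-based exposure flags.

FAERS drug names are uncodified free text: brand names, generics,
combinations and misspellings all occur.  Normalization runs a cascade —
exact archive lookup on a punctuation/case-normalized token, retry after
stripping dose and formulation suffixes, then an optional bounded
edit-distance rescue — and resolves to an International Nonproprietary
Name (INN).  INNs are indexed to ATC codes so reports can be flagged as
anticancer-exposed (any L01 code) and as exposed to the five CML
tyrosine-kinase inhibitors under study.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "DrugArchive",
    "ExposureFlags",
    "STUDY_TKIS",
    "normalize_name",
    "resolve_components",
    "mapping_coverage",
    "flag_exposures",
]

#: the five BCR-ABL TKIs with a European CML authorization
STUDY_TKIS = frozenset({"imatinib", "dasatinib", "bosutinib", "nilotinib", "ponatinib"})

_DOSE_RE = re.compile(r"^\d+(\.\d+)?(mg|mcg|g|ml|iu|%)?$")
_FORM_WORDS = {
    "mg", "mcg", "g", "ml", "iu",
    "tablet", "tablets", "tab", "tabs", "capsule", "capsules", "cap", "caps",
    "injection", "inj", "oral", "solution", "susp", "suspension", "cream",
    "gel", "patch", "syrup", "hcl", "hydrochloride", "sodium", "mesylate",
    "film", "coated", "extended", "release", "er", "xr", "sr",
}
_PUNCT_RE = re.compile(r"[^\w\s+;/]")
_WS_RE = re.compile(r"\s+")


def _token(name: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    s = _PUNCT_RE.sub(" ", str(name).casefold())
    return _WS_RE.sub(" ", s).strip()


def _strip_suffixes(token: str) -> str:
    """Drop trailing dose / formulation words ("gleevec 400mg tablet" -> "gleevec")."""
    words = token.split(" ")
    while len(words) > 1 and (_DOSE_RE.match(words[-1]) or words[-1] in _FORM_WORDS):
        words.pop()
    return " ".join(words)


def _within_one_edit(a: str, b: str) -> bool:
    # bounded Levenshtein: substitution, insertion or deletion of one char
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # a is shorter by one: try deleting each char of b
    for i in range(lb):
        if b[:i] + b[i + 1 :] == a:
            return True
    return False


@dataclass
class DrugArchive:
    """Name archive: (brand or generic) token -> INN, and INN -> ATC codes.

    Lookup is case-insensitive and whitespace/punctuation-normalized.
    Every INN in the ATC index is also registered as its own name entry,
    so normalizing an INN is the identity.
    """

    entries: Dict[str, str] = field(default_factory=dict)
    atc_index: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {_token(k): _token(v) for k, v in self.entries.items()}
        self.atc_index = {_token(k): frozenset(v) for k, v in self.atc_index.items()}
        for inn in self.atc_index:
            self.entries.setdefault(inn, inn)
        for inn in set(self.entries.values()):
            self.entries.setdefault(inn, inn)

    @classmethod
    def from_files(cls, names_path: str | Path, atc_path: str | Path, sep: str = "\t") -> "DrugArchive":
        """Load from two delimited two-column files: (name, inn) and (inn, atc).

        The ATC file may repeat an INN to attach several codes.
        """
        entries: Dict[str, str] = {}
        for line in Path(names_path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            name, inn = line.split(sep)[:2]
            entries[name] = inn
        atc: Dict[str, set] = {}
        for line in Path(atc_path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            inn, code = line.split(sep)[:2]
            atc.setdefault(_token(inn), set()).add(code.strip().upper())
        return cls(entries=entries, atc_index={k: frozenset(v) for k, v in atc.items()})

    def lookup(self, token: str) -> Optional[str]:
        return self.entries.get(token)

    def atc_for(self, inn: str) -> FrozenSet[str]:
        return self.atc_index.get(_token(inn), frozenset())

    def is_anticancer(self, inn: str) -> bool:
        return any(code.startswith("L01") for code in self.atc_for(inn))


@dataclass(frozen=True)
class ExposureFlags:
    """Report-level anticancer / study-TKI exposure, over all drug roles."""

    is_anticancer: bool
    tki_set: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if self.tki_set and not self.is_anticancer:
            raise ValueError("TKI exposure implies anticancer exposure")


def normalize_name(
    verbatim: str,
    archive: DrugArchive,
    edit_distance_rescue: bool = False,
) -> Optional[str]:
    """Resolve one free-text drug name to an INN, or ``None`` if unresolved.

    Cascade: exact token match; match after stripping dose/formulation
    suffixes; and, when ``edit_distance_rescue`` is enabled, a unique
    archive neighbour within edit distance 1 (tokens of >= 6 characters
    only — short names are too easy to confuse).
    """
    token = _token(verbatim)
    if not token:
        return None
    hit = archive.lookup(token)
    if hit is not None:
        return hit
    stripped = _strip_suffixes(token)
    hit = archive.lookup(stripped)
    if hit is not None:
        return hit
    if edit_distance_rescue and len(stripped) >= 6:
        hits = {
            inn
            for key, inn in archive.entries.items()
            if abs(len(key) - len(stripped)) <= 1 and _within_one_edit(stripped, key)
        }
        if len(hits) == 1:
            return next(iter(hits))
    return None


def resolve_components(
    verbatim: str,
    archive: DrugArchive,
    edit_distance_rescue: bool = False,
) -> FrozenSet[str]:
    """Resolve a possibly multi-ingredient name ("X + Y") per component."""
    parts = re.split(r"[+;]", str(verbatim))
    if len(parts) == 1:
        inn = normalize_name(verbatim, archive, edit_distance_rescue)
        return frozenset() if inn is None else frozenset({inn})
    resolved = set()
    for part in parts:
        inn = normalize_name(part, archive, edit_distance_rescue)
        if inn is not None:
            resolved.add(inn)
    return frozenset(resolved)


def mapping_coverage(
    reports: Iterable,
    archive: DrugArchive,
    edit_distance_rescue: bool = False,
    top_n: int = 20,
) -> Tuple[Optional[float], List[Tuple[str, int]]]:
    """Fraction of drug records resolving to an INN, plus top unresolved tokens.

    Returns ``(None, [])`` when there are no drug records at all.  The
    unresolved-token list is the worklist for manual archive completion.
    """
    total = 0
    resolved = 0
    unresolved: Counter = Counter()
    for report in reports:
        for record in report.drugs:
            total += 1
            inns = resolve_components(record.verbatim_name, archive, edit_distance_rescue)
            if inns:
                resolved += 1
            else:
                unresolved[_token(record.verbatim_name)] += 1
    if total == 0:
        return None, []
    return resolved / total, unresolved.most_common(top_n)


def flag_exposures(
    report,
    archive: DrugArchive,
    edit_distance_rescue: bool = False,
) -> ExposureFlags:
    """Compute anticancer / TKI exposure flags for one report.

    All drug roles count (suspect, concomitant, interacting): the design
    includes any report carrying an anticancer drug in any role, and the
    comparator is defined on the same basis.  Multi-ingredient names
    contribute each resolved component.
    """
    anticancer = False
    tkis = set()
    for record in report.drugs:
        if record.inn:
            inns = frozenset(_token(p) for p in record.inn.split(";"))
        else:
            inns = resolve_components(record.verbatim_name, archive, edit_distance_rescue)
        for inn in inns:
            if archive.is_anticancer(inn):
                anticancer = True
                if inn in STUDY_TKIS:
                    tkis.add(inn)
    return ExposureFlags(is_anticancer=anticancer, tki_set=frozenset(tkis))


def annotate_reports(
    reports: Iterable,
    archive: DrugArchive,
    edit_distance_rescue: bool = False,
) -> None:
    """Fill ``inn`` and ``atc_codes`` on every drug record, in place."""
    for report in reports:
        for record in report.drugs:
            inns = resolve_components(record.verbatim_name, archive, edit_distance_rescue)
            if len(inns) == 1:
                record.inn = next(iter(inns))
                record.atc_codes = archive.atc_for(record.inn)
            elif inns:
                record.inn = ";".join(sorted(inns))
                record.atc_codes = frozenset().union(*(archive.atc_for(i) for i in inns))
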