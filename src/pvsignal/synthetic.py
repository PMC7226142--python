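"""FAERS-like synthetic report sets with known ground truth.

Real spontaneous-report corpora cannot be shipped, and real MedDRA
content is licensed, so every pipeline stage is exercised on generated
data instead: raw "$"-delimited table sets with the same structure as a
quarterly extract, together with a :class:`GroundTruth` sidecar carrying
exactly what was planted — per-report seriousness, duplicate/follow-up
lineage, aberrant chronology, the realized 2x2 counts per drug-event
pair, and the per-case time-to-onset draws.

The structural model (``mode='logistic'``) draws, per report: covariates
(age class and sex, with explicit unknowns) -> exposure to the TKI group
through a logistic link with covariate log-odds shifts -> one anticancer
primary-suspect drug -> case status per event query through a second
logistic link whose exposure effect is ``log(true_or[drug, smq])``.
Planted odds ratios are therefore *conditional* (given age class and
sex): the estimand the adjusted analysis should recover.  A stratified
mode instead draws covariates per exposure group from explicit tables
and event status from per-drug case probabilities — used by the
reference preset that emulates the margins of a published FAERS CML-TKI
cardiovascular cohort.

Everything is deterministic under a fixed seed and configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .disproportionality import TKI_CLASS, ContingencyTable, ScreenInputs
from .drug_mapping import STUDY_TKIS, DrugArchive
from .faers_io import AGE_CLASSES, RawTableSet, write_table_set
from .smq import STUDY_SMQS, SMQCatalogue, SMQDefinition

__all__ = [
    "DrugSpec",
    "SMQSpec",
    "Confounding",
    "ScenarioConfig",
    "GroundTruth",
    "simulate_cohort",
    "generate",
    "build_archive",
    "build_catalogue",
    "default_scenario",
    "recovery_scenario",
    "null_scenario",
    "reference_cohort_preset",
    "screen_inputs_from_cohort",
]

_EPOCH = _dt.date(2008, 1, 1)
_START_SPAN_DAYS = 3652  # therapy starts drawn over 2008-2017

_AGE_BOUNDS = {"<=25": (1, 25), "26-50": (26, 50), "51-75": (51, 75), ">=76": (76, 95)}

_SEX_CODES = {"female": "F", "male": "M", "unknown": ""}

_OUTCOME_MENU = ("HO", "OT", "DE", "LT", "DS", "RI", "CA")
_OUTCOME_PROBS = (0.370, 0.424, 0.129, 0.051, 0.017, 0.0085, 0.0005)

_COUNTRY_MENU = ("US", "JP", "DE", "FR", "GB", "IT", "CA", "unknown")
_COUNTRY_PROBS = (0.360, 0.097, 0.073, 0.075, 0.09, 0.09, 0.195, 0.02)

_REPORTER_MENU = ("MD", "CN", "")
_REPORTER_PROBS = (0.739, 0.216, 0.045)

#: fictional non-event decoy preferred terms (never in any SMQ)
_DECOY_TERMS = tuple(f"Synthetic background reaction {i:02d}" for i in range(1, 31))

#: resolvable non-anticancer concomitants (fictional INN, brand, ATC)
_CONCO_MENU = (
    ("omeprazine", ("Gastrofix",), ("A02BC99",)),
    ("paracetamive", ("Dolorex",), ("N02BE99",)),
    ("lisinoprat", ("Pressurin",), ("C09AA99",)),
    ("metformide", ("Glucostat",), ("A10BA99",)),
    ("atorvastine", ("Lipidown",), ("C10AA99",)),
    ("levothyroxate", ("Thyronorm",), ("H03AA99",)),
)


@dataclass(frozen=True)
class DrugSpec:
    """One drug on the menu: identity, names, ATC and marginal share."""

    inn: str
    brands: Tuple[str, ...]
    atc: Tuple[str, ...]
    share: float
    case_prob: Optional[float] = None  # stratified mode: P(any CV case | drug)
    indication: str = "neoplasm malignant"

    @property
    def is_tki(self) -> bool:
        return self.inn in STUDY_TKIS


@dataclass(frozen=True)
class SMQSpec:
    """One event query: fictional scoped terms and baseline event probability."""

    name: str
    narrow_terms: Tuple[str, ...]
    broad_terms: Tuple[str, ...]
    baseline_p: float
    share_tki: Optional[float] = None  # stratified mode: share of TKI cases
    share_comp: Optional[float] = None


@dataclass(frozen=True)
class Confounding:
    """Log-odds shifts of covariates on exposure and on outcome."""

    age_exposure: Mapping[str, float] = field(default_factory=dict)
    sex_exposure: Mapping[str, float] = field(default_factory=dict)
    age_outcome: Mapping[str, float] = field(default_factory=dict)
    sex_outcome: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def none(cls) -> "Confounding":
        return cls()


@dataclass
class ScenarioConfig:
    """Full specification of one synthetic study scenario."""

    n_reports: int
    drug_menu: Tuple[DrugSpec, ...]
    smq_menu: Tuple[SMQSpec, ...]
    true_or: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    confounding: Confounding = field(default_factory=Confounding.none)
    mode: str = "logistic"  # or "stratified"
    age_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "<=25": 0.045,
            "26-50": 0.116,
            "51-75": 0.448,
            ">=76": 0.111,
            "unknown": 0.280,
        }
    )
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.446, "male": 0.421, "unknown": 0.133}
    )
    # stratified mode: per-exposure-group covariate tables
    age_class_probs_tki: Optional[Mapping[str, float]] = None
    sex_probs_tki: Optional[Mapping[str, float]] = None
    dup_rate: float = 0.05
    followup_rate: float = 0.05
    aberrant_rate: float = 0.02
    nonserious_rate: float = 0.10
    missing_date_rate: float = 0.25
    misspell_rate: float = 0.02
    unresolvable_conco_rate: float = 0.20
    max_concomitants: int = 2
    tto_scale_days: Mapping[str, float] = field(default_factory=dict)  # inn -> exp. mean
    default_tto_scale: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "dup_rate": self.dup_rate,
            "followup_rate": self.followup_rate,
            "aberrant_rate": self.aberrant_rate,
            "nonserious_rate": self.nonserious_rate,
            "missing_date_rate": self.missing_date_rate,
            "misspell_rate": self.misspell_rate,
            "unresolvable_conco_rate": self.unresolvable_conco_rate,
        }
        for name, p in rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if abs(sum(d.share for d in self.drug_menu) - 1) > 1e-9:
            raise ValueError("drug shares must sum to 1")
        for pair, or_ in self.true_or.items():
            if or_ <= 0:
                raise ValueError(f"true odds ratio for {pair} must be positive")
        if self.mode not in {"logistic", "stratified"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.nonserious_rate + self.aberrant_rate >= 1:
            raise ValueError("nonserious and aberrant rates leave no retained reports")
        for probs in (self.age_class_probs, self.sex_probs):
            if abs(sum(probs.values()) - 1) > 1e-9:
                raise ValueError("covariate probabilities must sum to 1")


def _pick(rng: np.random.Generator, menu: Sequence[str], probs: Sequence[float], n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(menu, dtype=object), size=n, p=p / p.sum())


def simulate_cohort(config: ScenarioConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw the base cohort: one row per underlying report, all ground truth.

    Columns include demographics, the primary anticancer drug, per-query
    case flags (``smqcase_<smq>``), the planted seriousness/aberrant flags
    and the true time-to-onset draw.  Clone injection (duplicates and
    follow-ups) happens later, at table-writing time, and never changes
    these rows.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = list(config.drug_menu)
    shares = np.array([d.share for d in drugs])
    tki_mask = np.array([d.is_tki for d in drugs])

    if config.mode == "logistic":
        age_class = _pick(rng, list(config.age_class_probs), list(config.age_class_probs.values()), n)
        sex = _pick(rng, list(config.sex_probs), list(config.sex_probs.values()), n)
        p_tki_base = shares[tki_mask].sum()
        eta = logit(p_tki_base)
        eta = eta + np.array([config.confounding.age_exposure.get(a, 0.0) for a in age_class])
        eta = eta + np.array([config.confounding.sex_exposure.get(s, 0.0) for s in sex])
        is_tki = rng.random(n) < expit(eta)
        drug = np.empty(n, dtype=object)
        for group_mask, member in ((is_tki, True), (~is_tki, False)):
            pool = [d for d, m in zip(drugs, tki_mask) if m == member]
            w = np.array([d.share for d in pool])
            idx = rng.choice(len(pool), size=int(group_mask.sum()), p=w / w.sum())
            drug[group_mask] = np.array([d.inn for d in pool], dtype=object)[idx]
    else:  # stratified
        idx = rng.choice(len(drugs), size=n, p=shares)
        drug = np.array([d.inn for d in drugs], dtype=object)[idx]
        is_tki = tki_mask[idx]
        age_class = np.empty(n, dtype=object)
        sex = np.empty(n, dtype=object)
        for mask, age_probs, sex_probs in (
            (is_tki, config.age_class_probs_tki or config.age_class_probs,
             config.sex_probs_tki or config.sex_probs),
            (~is_tki, config.age_class_probs, config.sex_probs),
        ):
            m = int(mask.sum())
            age_class[mask] = _pick(rng, list(age_probs), list(age_probs.values()), m)
            sex[mask] = _pick(rng, list(sex_probs), list(sex_probs.values()), m)

    age_years = np.full(n, np.nan)
    for cls, (lo, hi) in _AGE_BOUNDS.items():
        mask = age_class == cls
        age_years[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    case_prob_by_inn = {d.inn: d.case_prob for d in drugs}
    case_cols: Dict[str, np.ndarray] = {}
    for smq in config.smq_menu:
        if config.mode == "logistic":
            eta = logit(smq.baseline_p) * np.ones(n)
            for d in drugs:
                or_ = config.true_or.get((d.inn, smq.name), 1.0)
                if or_ != 1.0:
                    eta = eta + np.where(drug == d.inn, np.log(or_), 0.0)
            eta = eta + np.array([config.confounding.age_outcome.get(a, 0.0) for a in age_class])
            eta = eta + np.array([config.confounding.sex_outcome.get(s, 0.0) for s in sex])
            p = expit(eta)
        else:
            share = np.where(is_tki, smq.share_tki or 0.0, smq.share_comp or 0.0)
            p_any = np.array([case_prob_by_inn[d] or 0.0 for d in drug])
            # split the any-case probability across queries so that the
            # union over independent queries reproduces it exactly
            p = 1.0 - np.power(1.0 - p_any, share)
        case_cols[f"smqcase_{smq.name}"] = rng.random(n) < p

    any_case = np.zeros(n, dtype=bool)
    for col in case_cols.values():
        any_case |= col

    serious = rng.random(n) >= config.nonserious_rate
    # aberrant chronology only planted on serious reports with full dates
    aberrant = (rng.random(n) < config.aberrant_rate) & serious

    tto_scale = np.array(
        [config.tto_scale_days.get(d, config.default_tto_scale) for d in drug]
    )
    tto_days = np.floor(rng.exponential(tto_scale)).astype(int)
    noncase_gap = rng.integers(0, 366, size=n)
    gap = np.where(any_case, tto_days, noncase_gap)

    start_offset = rng.integers(0, _START_SPAN_DAYS, size=n)
    onset_offset = start_offset + gap
    fda_offset = onset_offset + rng.integers(5, 61, size=n)

    # date completeness: 0 full, 1 year-month, 2 missing (aberrant kept full)
    def _date_state() -> np.ndarray:
        u = rng.random(n)
        state = np.zeros(n, dtype=int)
        state[u < config.missing_date_rate] = 1
        state[u < config.missing_date_rate * 0.7] = 2
        state[aberrant] = 0
        return state

    start_state = _date_state()
    onset_state = _date_state()

    clone_u = rng.random(n)
    eligible_clone = serious & ~aberrant
    has_followup = eligible_clone & (clone_u < config.followup_rate)
    has_duplicate = eligible_clone & (
        (clone_u >= config.followup_rate)
        & (clone_u < config.followup_rate + config.dup_rate)
    )

    cohort = pd.DataFrame(
        {
            "case_id": [f"{1000000 + i}" for i in range(n)],
            "report_id": [f"{1000000 + i}1" for i in range(n)],
            "age_class": age_class,
            "age_years": age_years,
            "sex": sex,
            "country": _pick(rng, _COUNTRY_MENU, _COUNTRY_PROBS, n),
            "reporter": _pick(rng, _REPORTER_MENU, _REPORTER_PROBS, n),
            "drug": drug,
            "is_tki": is_tki,
            "serious": serious,
            "aberrant": aberrant,
            "has_followup": has_followup,
            "has_duplicate": has_duplicate,
            "start_offset": start_offset,
            "onset_offset": onset_offset,
            "fda_offset": fda_offset,
            "start_state": start_state,
            "onset_state": onset_state,
            "tto_days": gap,
            **case_cols,
        }
    )
    cohort["retained"] = cohort["serious"] & ~cohort["aberrant"]
    return cohort


def _offset_to_str(offset: int, state: int) -> str:
    if state == 2:
        return ""
    d = _EPOCH + _dt.timedelta(days=int(offset))
    if state == 1:
        return f"{d.year:04d}{d.month:02d}"
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def _misspell(name: str, rng: np.random.Generator) -> str:
    """Delete one interior character: guaranteed edit distance 1."""
    if len(name) < 8:
        return name
    i = int(rng.integers(1, len(name) - 1))
    return name[:i] + name[i + 1 :]


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact pipeline checks."""

    cohort: pd.DataFrame
    config: ScenarioConfig
    n_input: int
    n_nonserious: int
    n_duplicates: int  # superseded follow-up versions + duplicate clones
    n_aberrant: int
    n_retained: int
    n_drug_records: int = 0
    n_resolvable_records: int = 0

    def contingency(self, index_drug: str, smq_name: str) -> ContingencyTable:
        """Realized a/b/c/d among retained reports, by construction."""
        kept = self.cohort[self.cohort["retained"]]
        case = kept[f"smqcase_{smq_name}"].to_numpy()
        if index_drug == TKI_CLASS:
            exposed = kept["is_tki"].to_numpy()
        else:
            exposed = (kept["drug"] == index_drug).to_numpy()
        return ContingencyTable(
            int((case & exposed).sum()),
            int((~case & exposed).sum()),
            int((case & ~exposed).sum()),
            int((~case & ~exposed).sum()),
        )

    @property
    def design_coverage(self) -> Optional[float]:
        if self.n_drug_records == 0:
            return None
        return self.n_resolvable_records / self.n_drug_records


def build_archive(config: ScenarioConfig) -> DrugArchive:
    """The name archive matching the scenario's drug menu (plus decoys)."""
    entries: Dict[str, str] = {}
    atc: Dict[str, FrozenSet[str]] = {}
    for d in list(config.drug_menu):
        for brand in d.brands:
            entries[brand] = d.inn
        atc[d.inn] = frozenset(d.atc)
    for inn, brands, codes in _CONCO_MENU:
        for brand in brands:
            entries[brand] = inn
        atc[inn] = frozenset(codes)
    return DrugArchive(entries=entries, atc_index=atc)


def build_catalogue(config: ScenarioConfig) -> SMQCatalogue:
    """The SMQ term catalogue matching the scenario's event menu."""
    defs = {}
    for smq in config.smq_menu:
        terms = {t.casefold(): "narrow" for t in smq.narrow_terms}
        terms.update({t.casefold(): "broad" for t in smq.broad_terms})
        defs[smq.name] = SMQDefinition(name=smq.name, terms=terms)
    return SMQCatalogue(defs)


def generate(
    config: ScenarioConfig,
    out_dir: Optional[str | Path] = None,
) -> Tuple[RawTableSet, GroundTruth]:
    """Emit a complete raw table set (and sidecar ground truth).

    Duplicate clones share every duplicate-key field with their source
    and differ only in identifiers; follow-up clones re-issue the case
    under a higher version.  Base reports are guaranteed key-unique (a
    synthetic marker term is appended on collision), so preprocessing
    removal counts equal the injected counts exactly.
    """
    rng = np.random.default_rng(config.seed)
    cohort = simulate_cohort(config, rng)
    n = len(cohort)
    drug_by_inn = {d.inn: d for d in config.drug_menu}
    smq_by_name = {s.name: s for s in config.smq_menu}
    case_cols = [c for c in cohort.columns if c.startswith("smqcase_")]

    # per-report event term lists
    terms: List[List[str]] = []
    for i in range(n):
        row_terms: List[str] = []
        for col in case_cols:
            if cohort[col].iat[i]:
                spec = smq_by_name[col[len("smqcase_") :]]
                row_terms.append(spec.narrow_terms[int(rng.integers(len(spec.narrow_terms)))])
        if not row_terms or rng.random() < 0.3:
            row_terms.append(_DECOY_TERMS[int(rng.integers(len(_DECOY_TERMS)))])
        terms.append(row_terms)

    # uniquify duplicate keys among base reports
    def _key(i: int) -> tuple:
        onset = _offset_to_str(cohort["onset_offset"].iat[i], cohort["onset_state"].iat[i])
        age = cohort["age_years"].iat[i]
        return (
            tuple(sorted({t.casefold() for t in terms[i]})),
            onset,
            None if np.isnan(age) else float(age),
            cohort["sex"].iat[i],
            cohort["country"].iat[i],
        )

    seen: Dict[tuple, int] = {}
    for i in range(n):
        k = _key(i)
        while k in seen:
            terms[i] = terms[i] + [f"Synthetic marker reaction {i:06d}"]
            k = _key(i)
        seen[k] = i

    # drug-name rendering for the primary drug
    def _render_name(spec: DrugSpec) -> str:
        u = rng.random()
        if u < config.misspell_rate:
            return _misspell(spec.inn, rng).upper()
        if u < 0.5 and spec.brands:
            name = spec.brands[int(rng.integers(len(spec.brands)))]
            if rng.random() < 0.3:
                name = f"{name} {int(rng.integers(1, 9)) * 100}MG"
            return name.upper()
        return spec.inn.upper()

    demo_rows, drug_rows, reac_rows, outc_rows, indi_rows, ther_rows = [], [], [], [], [], []
    n_drug_records = 0
    n_resolvable = 0

    def _emit(i: int, primaryid: str, caseid: str, caseversion: int) -> None:
        nonlocal n_drug_records, n_resolvable
        row = cohort.iloc[i]
        age = row["age_years"]
        demo_rows.append(
            {
                "primaryid": primaryid,
                "caseid": caseid,
                "caseversion": str(caseversion),
                "event_dt": _offset_to_str(row["onset_offset"], row["onset_state"]),
                "age": "" if np.isnan(age) else str(int(age)),
                "age_cod": "" if np.isnan(age) else "YR",
                "sex": _SEX_CODES[row["sex"]],
                "occp_cod": row["reporter"],
                "reporter_country": "" if row["country"] == "unknown" else row["country"],
                "fda_dt": _offset_to_str(row["fda_offset"], 0),
            }
        )
        spec = drug_by_inn[row["drug"]]
        drug_rows.append(
            {
                "primaryid": primaryid,
                "caseid": caseid,
                "drug_seq": "1",
                "role_cod": "PS" if rng.random() < 0.85 else ("SS" if rng.random() < 0.9 else "C"),
                "drugname": _render_name(spec),
            }
        )
        n_drug_records += 1
        n_resolvable += 1
        ther_rows.append(
            {
                "primaryid": primaryid,
                "caseid": caseid,
                "dsg_drug_seq": "1",
                "start_dt": _offset_to_str(row["start_offset"], row["start_state"]),
                "end_dt": "",
            }
        )
        indi_rows.append(
            {
                "primaryid": primaryid,
                "caseid": caseid,
                "indi_drug_seq": "1",
                "indi_pt": spec.indication,
            }
        )
        n_conco = int(rng.integers(0, config.max_concomitants + 1))
        for j in range(n_conco):
            if rng.random() < config.unresolvable_conco_rate:
                name = f"UNLISTED REMEDY {int(rng.integers(100)):02d}"
            else:
                conco = _CONCO_MENU[int(rng.integers(len(_CONCO_MENU)))]
                name = (conco[0] if rng.random() < 0.5 else conco[1][0]).upper()
                n_resolvable += 1
            n_drug_records += 1
            drug_rows.append(
                {
                    "primaryid": primaryid,
                    "caseid": caseid,
                    "drug_seq": str(j + 2),
                    "role_cod": "C",
                    "drugname": name,
                }
            )
        for t in terms[i]:
            reac_rows.append({"primaryid": primaryid, "caseid": caseid, "pt": t})
        if row["serious"]:
            code = _OUTCOME_MENU[
                int(rng.choice(len(_OUTCOME_MENU), p=np.asarray(_OUTCOME_PROBS) / sum(_OUTCOME_PROBS)))
            ]
            outc_rows.append({"primaryid": primaryid, "caseid": caseid, "outc_cod": code})

    # aberrant chronology: swap so therapy starts strictly after the event
    swap = cohort["aberrant"].to_numpy()
    start, onset = cohort["start_offset"].to_numpy().copy(), cohort["onset_offset"].to_numpy().copy()
    start[swap], onset[swap] = onset[swap] + 1 + (start[swap] % 120), onset[swap]
    cohort = cohort.assign(start_offset=start, onset_offset=onset)

    n_followups = 0
    n_dup_clones = 0
    for i in range(n):
        caseid = cohort["case_id"].iat[i]
        _emit(i, f"{caseid}1", caseid, 1)
        if cohort["has_followup"].iat[i]:
            _emit(i, f"{caseid}2", caseid, 2)
            n_followups += 1
        if cohort["has_duplicate"].iat[i]:
            dup_caseid = f"{5000000 + i}"
            _emit(i, f"{dup_caseid}1", dup_caseid, 1)
            n_dup_clones += 1

    tables = RawTableSet(
        demo=pd.DataFrame(demo_rows),
        drug=pd.DataFrame(drug_rows),
        reac=pd.DataFrame(reac_rows),
        outc=pd.DataFrame(outc_rows),
        indi=pd.DataFrame(indi_rows),
        ther=pd.DataFrame(ther_rows),
        source_quarter="synthetic",
    )
    truth = GroundTruth(
        cohort=cohort,
        config=config,
        n_input=len(demo_rows),
        n_nonserious=int((~cohort["serious"]).sum()),
        n_duplicates=n_followups + n_dup_clones,
        n_aberrant=int(cohort["aberrant"].sum()),
        n_retained=int(cohort["retained"].sum()),
        n_drug_records=n_drug_records,
        n_resolvable_records=n_resolvable,
    )
    if out_dir is not None:
        write_table_set(tables, out_dir)
    return tables, truth


def screen_inputs_from_cohort(cohort: pd.DataFrame) -> ScreenInputs:
    """Ground-truth screen inputs straight from the cohort frame.

    Bypasses file round-tripping for large simulation studies: the frame
    already holds exposure, covariates and case labels for the retained
    reports, so estimator behaviour can be studied at scale.
    """
    kept = cohort[cohort["retained"]].set_index("report_id")
    case_cols = [c for c in kept.columns if c.startswith("smqcase_")]
    labels = kept[case_cols].rename(columns=lambda c: c[len("smqcase_") :]).astype(bool)
    exposures = pd.Series(
        [frozenset({d}) if tki else frozenset() for d, tki in zip(kept["drug"], kept["is_tki"])],
        index=kept.index,
    )
    covariates = kept[["age_class", "sex"]]
    return ScreenInputs(labels=labels, exposures=exposures, covariates=covariates)


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------


def _study_smq_menu(baselines: Optional[Mapping[str, float]] = None) -> Tuple[SMQSpec, ...]:
    """Eight study queries with fictional terms; baselines per comparator rates."""
    default_baselines = {
        "cardiac failure": 0.012,
        "cardiomyopathy": 0.005,
        "hypertension": 0.012,
        "pulmonary hypertension": 0.0012,
        "ischaemic heart disease": 0.013,
        "torsade de pointes/QT prolongation": 0.0012,
        "cardiac arrhythmias": 0.003,
        "embolic and thrombotic events": 0.040,
    }
    baselines = dict(baselines or default_baselines)
    menu = []
    for name in STUDY_SMQS:
        menu.append(
            SMQSpec(
                name=name,
                narrow_terms=tuple(f"Synthetic {name} sign {i}" for i in range(1, 5)),
                broad_terms=tuple(f"Synthetic {name} hint {i}" for i in range(1, 3)),
                baseline_p=baselines[name],
            )
        )
    return tuple(menu)


def _study_drug_menu(tki_share: float = 0.034) -> Tuple[DrugSpec, ...]:
    """Five TKIs (menu shares per the reference cohort) plus comparators."""
    tki_weights = {
        "nilotinib": 0.465,
        "dasatinib": 0.296,
        "ponatinib": 0.127,
        "imatinib": 0.101,
        "bosutinib": 0.011,
    }
    brands = {
        "nilotinib": ("Tasigna",),
        "dasatinib": ("Sprycel",),
        "ponatinib": ("Iclusig",),
        "imatinib": ("Gleevec", "Glivec"),
        "bosutinib": ("Bosulif",),
    }
    menu = [
        DrugSpec(
            inn=inn,
            brands=brands[inn],
            atc=("L01XE",),
            share=tki_share * w,
            indication="chronic myeloid leukaemia",
        )
        for inn, w in tki_weights.items()
    ]
    comparators = (
        ("paclitaxel", ("Taxol",)),
        ("rituximab", ("Rituxan",)),
        ("bevacizumab", ("Avastin",)),
        ("cyclophosphamide", ("Cytoxan",)),
        ("doxorubicin", ("Adriamycin",)),
        ("trastuzumab", ("Herceptin",)),
        ("fluorouracil", ("Adrucil",)),
    )
    w_comp = (1 - tki_share) / len(comparators)
    menu.extend(
        DrugSpec(inn=inn, brands=b, atc=("L01X",), share=w_comp) for inn, b in comparators
    )
    return tuple(menu)


def default_scenario(n_reports: int = 20000, seed: int = 0, **overrides) -> ScenarioConfig:
    """The all-purpose scenario: study margins, no planted signals."""
    cfg = ScenarioConfig(
        n_reports=n_reports,
        drug_menu=_study_drug_menu(),
        smq_menu=_study_smq_menu(),
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def null_scenario(n_reports: int = 50000, seed: int = 0) -> ScenarioConfig:
    """All true odds ratios 1 (with confounding off): type-I-error study."""
    return default_scenario(n_reports=n_reports, seed=seed)


#: covariate shifts used by the recovery scenario: age and sex drive both
#: TKI prescription and cardiovascular reporting, inflating the crude ROR
_RECOVERY_CONFOUNDING = Confounding(
    age_exposure={"<=25": -0.7, "51-75": 0.7, ">=76": 1.1},
    sex_exposure={"male": 0.5},
    age_outcome={"<=25": -0.9, "51-75": 0.7, ">=76": 1.2},
    sex_outcome={"male": 0.4},
)


def recovery_scenario(
    n_reports: int = 50000,
    true_or: float = 12.0,
    drug: str = "nilotinib",
    smq: str = "torsade de pointes/QT prolongation",
    seed: int = 0,
) -> ScenarioConfig:
    """Parameter-recovery scenario: one planted conditional OR, confounded.

    The index drug's menu share (5%) and the event baseline (1%) are
    chosen so cell counts are comfortably in the Wald-asymptotic regime;
    what is under test is estimator calibration, not sparse-cell
    behaviour (which the null scenario covers).
    """
    tki_weights = {"nilotinib": 0.0, "dasatinib": 0.01, "ponatinib": 0.01,
                   "imatinib": 0.02, "bosutinib": 0.01}
    tki_weights[drug] = 0.05
    total_tki = sum(tki_weights.values())
    menu = []
    for spec in _study_drug_menu():
        if spec.is_tki:
            menu.append(dataclasses.replace(spec, share=tki_weights[spec.inn]))
        else:
            menu.append(dataclasses.replace(spec, share=spec.share / 0.966 * (1 - total_tki)))
    baselines = {name: 0.01 for name in STUDY_SMQS}
    return ScenarioConfig(
        n_reports=n_reports,
        drug_menu=tuple(menu),
        smq_menu=_study_smq_menu(baselines),
        true_or={(drug, smq): true_or},
        confounding=_RECOVERY_CONFOUNDING,
        seed=seed,
    )


def reference_cohort_preset(n_reports: int = 100000, seed: int = 0) -> ScenarioConfig:
    """Margins emulating the published FAERS CML-TKI cardiovascular cohort.

    Stratified mode: drug shares follow the cohort's TKI report mix,
    per-drug any-CV-case probabilities reproduce each drug's observed
    case fraction (so e.g. the expected nilotinib share of TKI cases is
    2319/3930 = 59.0%), and covariate tables differ between the TKI and
    comparator groups (expected male share of TKI cases 52.9%).
    """
    # cases / (cases + non-cases) per TKI in the reference cohort
    case_probs = {
        "nilotinib": 2319 / 11333,
        "dasatinib": 835 / 7217,
        "ponatinib": 565 / 3101,
        "imatinib": 173 / 2464,
        "bosutinib": 38 / 258,
    }
    comp_case_prob = 60302 / 692790
    smq_share_tki = {
        "cardiac arrhythmias": 126,
        "cardiac failure": 669,
        "cardiomyopathy": 78,
        "embolic and thrombotic events": 1049,
        "hypertension": 306,
        "ischaemic heart disease": 1306,
        "pulmonary hypertension": 127,
        "torsade de pointes/QT prolongation": 269,
    }
    smq_share_comp = {
        "cardiac arrhythmias": 1982,
        "cardiac failure": 8402,
        "cardiomyopathy": 3238,
        "embolic and thrombotic events": 27911,
        "hypertension": 8236,
        "ischaemic heart disease": 8833,
        "pulmonary hypertension": 854,
        "torsade de pointes/QT prolongation": 846,
    }
    t_tot = sum(smq_share_tki.values())
    c_tot = sum(smq_share_comp.values())
    # exact report totals per TKI, as fractions of the full cohort
    tki_reports = {
        "nilotinib": 11333,
        "dasatinib": 7217,
        "ponatinib": 3101,
        "imatinib": 2464,
        "bosutinib": 258,
    }
    menu = []
    for spec in _study_drug_menu(tki_share=24373 / 717163):
        if spec.is_tki:
            menu.append(
                dataclasses.replace(
                    spec,
                    share=tki_reports[spec.inn] / 717163,
                    case_prob=case_probs[spec.inn],
                )
            )
        else:
            menu.append(dataclasses.replace(spec, case_prob=comp_case_prob))
    smq_menu = tuple(
        dataclasses.replace(
            s,
            share_tki=smq_share_tki[s.name] / t_tot,
            share_comp=smq_share_comp[s.name] / c_tot,
        )
        for s in _study_smq_menu()
    )
    return ScenarioConfig(
        n_reports=n_reports,
        drug_menu=tuple(menu),
        smq_menu=smq_menu,
        mode="stratified",
        age_class_probs_tki={"<=25": 0.010, "26-50": 0.111, "51-75": 0.440, ">=76": 0.125, "unknown": 0.314},
        age_class_probs={"<=25": 0.048, "26-50": 0.116, "51-75": 0.449, ">=76": 0.110, "unknown": 0.277},
        sex_probs_tki={"female": 0.362, "male": 0.529, "unknown": 0.109},
        sex_probs={"female": 0.451, "male": 0.414, "unknown": 0.135},
        seed=seed,
    )
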