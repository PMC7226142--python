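"""Reporting Odds Ratio disproportionality with covariate adjustment.

The case/non-case design treats a spontaneous-report database as a
cross-section: for one drug and one event definition, reports split
into the 2x2 table

=================  =====  =========
..                 cases  non-cases
=================  =====  =========
index drug         a      b
comparator drugs   c      d
=================  =====  =========

and the Reporting Odds Ratio is ``ROR = (a*d) / (b*c)`` with the Woolf
(log-scale Wald) 95% confidence interval
``exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.

Age and sex distort reporting odds when they drive both drug choice and
event risk, so an adjusted ROR (aROR) is estimated as the exposure
coefficient of a maximum-likelihood logistic regression
``case ~ exposure + age_class + sex`` over the comparator population;
"unknown" age and sex are kept as explicit covariate levels because
spontaneous reports are heavily incomplete.

Screening conventions follow standard pharmacovigilance practice: a
drug-event pair enters the analysis only with at least 3 exposed cases,
and a Signal of Disproportionate Reporting (SDR) is flagged when the
lower 95% bound of the adjusted ROR exceeds 1.

The modelling surface mimics statsmodels: build a
:class:`CaseNonCaseModel` from arrays or a DataFrame, call ``fit()``,
and read estimates, intervals and diagnostics off the returned
:class:`DisproportionalityResult` (or print ``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .drug_mapping import STUDY_TKIS
from .faers_io import AGE_CLASSES

__all__ = [
    "TKI_CLASS",
    "ContingencyTable",
    "Estimate",
    "ZeroCellError",
    "crude_ror",
    "build_table",
    "CaseNonCaseModel",
    "DisproportionalityResult",
    "adjusted_ror",
    "ScreenInputs",
    "screen_all",
]

#: pseudo-drug naming the pooled five-TKI class analysis
TKI_CLASS = "TKI class"

_SEX_LEVELS = ("female", "male", "unknown")



class ZeroCellError(ValueError):
    """A margin cell needed by the Woolf interval is zero."""


@dataclass(frozen=True)
class ContingencyTable:
    """Case/non-case x index/comparator counts for one drug-event pair."""

    a: int  # cases exposed to the index drug
    b: int  # non-cases exposed to the index drug
    c: int  # cases among comparator reports
    d: int  # non-cases among comparator reports

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """Exchange index and comparator rows (inverts the ROR)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class Estimate:
    """A ratio estimate with its two-sided confidence interval."""

    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError("interval must bracket the estimate")


def crude_ror(table: ContingencyTable, alpha: float = 0.05) -> Estimate:
    """Crude ROR with its Woolf confidence interval.

    No continuity correction is applied: a zero in b, c or d raises
    :class:`ZeroCellError` and the pair is reported as not computable.
    (A zero in a is allowed by the formula only for the point estimate;
    the CI needs all four cells, so it raises too.)
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        raise ZeroCellError(f"zero cell in table a={a} b={b} c={c} d={d}")
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return Estimate(ror, math.exp(math.log(ror) - z * se), math.exp(math.log(ror) + z * se))


def build_table(
    labels: Mapping[str, bool] | pd.Series,
    exposures: Mapping[str, FrozenSet[str]] | pd.Series,
    index_drug: str,
) -> ContingencyTable:
    """Count the 2x2 table for one SMQ's case labels and one index drug.

    ``labels`` maps report_id -> is_case for the SMQ; ``exposures`` maps
    report_id -> set of study-TKI INNs (empty for comparator anticancer
    reports).  Both must cover the same retained-report set.  A report
    exposed to the index drug counts in the index margin even when other
    anticancer drugs are present.  ``index_drug`` may be
    :data:`TKI_CLASS` to pool all five TKIs.
    """
    labels = pd.Series(labels)
    exposures = pd.Series(exposures)
    if set(labels.index) != set(exposures.index):
        raise ValueError("labels and exposures must cover the same report set")
    exposures = exposures.reindex(labels.index)
    if index_drug == TKI_CLASS:
        exposed = exposures.map(lambda s: len(s) > 0)
    else:
        exposed = exposures.map(lambda s: index_drug in s)
    case = labels.astype(bool)
    a = int((case & exposed).sum())
    b = int((~case & exposed).sum())
    c = int((case & ~exposed).sum())
    d = int((~case & ~exposed).sum())
    if c + d == 0:
        raise ValueError("empty comparator set: no reference reports")
    return ContingencyTable(a, b, c, d)


@dataclass
class DisproportionalityResult:
    """Fitted crude and adjusted RORs for one drug-event pair.

    ``sdr`` is True when the pair is eligible (>= ``min_cases`` exposed
    cases) and the adjusted ROR's lower 95% bound exceeds 1.
    """

    drug: str
    smq_name: str
    table: ContingencyTable
    eligible: bool
    crude: Optional[Estimate] = None
    crude_reason: Optional[str] = None
    adjusted: Optional[Estimate] = None
    adjusted_reason: Optional[str] = None
    nobs: int = 0
    converged: Optional[bool] = None

    @property
    def n_cases(self) -> int:
        return self.table.a

    @property
    def sdr(self) -> bool:
        return bool(self.eligible and self.adjusted is not None and self.adjusted.ci_low > 1)

    def as_dict(self) -> Dict[str, object]:
        t = self.table
        return {
            "drug": self.drug,
            "smq": self.smq_name,
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
            "crude_ror": self.crude.value if self.crude else None,
            "crude_ci_low": self.crude.ci_low if self.crude else None,
            "crude_ci_high": self.crude.ci_high if self.crude else None,
            "adj_ror": self.adjusted.value if self.adjusted else None,
            "adj_ci_low": self.adjusted.ci_low if self.adjusted else None,
            "adj_ci_high": self.adjusted.ci_high if self.adjusted else None,
            "eligible": self.eligible,
            "sdr": self.sdr,
        }

    def summary(self) -> str:
        """A compact, human-readable report of the fit."""
        t = self.table
        lines = [
            "Case/non-case disproportionality",
            "=" * 44,
            f"index drug      : {self.drug}",
            f"event query     : {self.smq_name}",
            f"table (a,b,c,d) : {t.a}, {t.b}, {t.c}, {t.d}",
            f"exposed cases   : {t.a} (eligible: {'yes' if self.eligible else 'no, < 3 cases'})",
        ]
        if self.crude:
            lines.append(
                f"crude ROR       : {self.crude.value:.2f} "
                f"(95% CI {self.crude.ci_low:.2f}-{self.crude.ci_high:.2f})"
            )
        else:
            lines.append(f"crude ROR       : not computed ({self.crude_reason})")
        if self.adjusted:
            lines.append(
                f"adjusted ROR    : {self.adjusted.value:.2f} "
                f"(95% CI {self.adjusted.ci_low:.2f}-{self.adjusted.ci_high:.2f})"
            )
        else:
            lines.append(f"adjusted ROR    : not computed ({self.adjusted_reason})")
        lines.append(f"SDR             : {'yes' if self.sdr else 'no'}")
        return "\n".join(lines)


class CaseNonCaseModel:
    """Case/non-case model for one drug-event pair over a comparator set.

    Parameters
    ----------
    is_case : array-like of bool
        Case status for the event definition, one entry per retained
        report in the analysis set (index-exposed plus comparator).
    exposed : array-like of bool
        Exposure to the index drug.
    age_class, sex : array-like of str, optional
        Covariates for the adjusted fit, coded with explicit "unknown"
        levels.  When omitted the adjusted fit reduces to the crude one.
    """

    def __init__(
        self,
        is_case,
        exposed,
        age_class=None,
        sex=None,
        *,
        drug: str = "drug",
        smq: str = "event",
        min_cases: int = 3,
    ) -> None:
        self.is_case = np.asarray(is_case, dtype=bool)
        self.exposed = np.asarray(exposed, dtype=bool)
        if self.is_case.shape != self.exposed.shape:
            raise ValueError("is_case and exposed must have the same length")
        self.age_class = None if age_class is None else np.asarray(age_class, dtype=object)
        self.sex = None if sex is None else np.asarray(sex, dtype=object)
        for name, arr in (("age_class", self.age_class), ("sex", self.sex)):
            if arr is not None and arr.shape != self.is_case.shape:
                raise ValueError(f"{name} must have the same length as is_case")
        self.drug = drug
        self.smq = smq
        self.min_cases = min_cases

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        case_col: str,
        exposure_col: str,
        age_col: Optional[str] = "age_class",
        sex_col: Optional[str] = "sex",
        **kwargs,
    ) -> "CaseNonCaseModel":
        return cls(
            data[case_col],
            data[exposure_col],
            data[age_col] if age_col and age_col in data else None,
            data[sex_col] if sex_col and sex_col in data else None,
            **kwargs,
        )

    @property
    def contingency(self) -> ContingencyTable:
        a = int((self.is_case & self.exposed).sum())
        b = int((~self.is_case & self.exposed).sum())
        c = int((self.is_case & ~self.exposed).sum())
        d = int((~self.is_case & ~self.exposed).sum())
        return ContingencyTable(a, b, c, d)

    def _design(self) -> pd.DataFrame:
        cols = {"const": np.ones(len(self.is_case)), "exposed": self.exposed.astype(float)}
        # reference levels: first age class and "female"; unknown kept as a level
        if self.age_class is not None:
            levels = [l for l in AGE_CLASSES if l in set(self.age_class)]
            for level in levels[1:]:
                cols[f"age[{level}]"] = (self.age_class == level).astype(float)
        if self.sex is not None:
            levels = [l for l in _SEX_LEVELS if l in set(self.sex)]
            for level in levels[1:]:
                cols[f"sex[{level}]"] = (self.sex == level).astype(float)
        return pd.DataFrame(cols)

    def fit(self, adjusted: bool = True, alpha: float = 0.05) -> DisproportionalityResult:
        """Fit crude (and, by default, covariate-adjusted) RORs."""
        table = self.contingency
        result = DisproportionalityResult(
            drug=self.drug,
            smq_name=self.smq,
            table=table,
            eligible=table.a >= self.min_cases,
            nobs=table.n,
        )
        try:
            result.crude = crude_ror(table, alpha=alpha)
        except ZeroCellError as exc:
            result.crude_reason = str(exc)
        if not adjusted:
            result.adjusted_reason = "adjusted fit not requested"
            return result
        if table.a < self.min_cases:
            result.adjusted_reason = f"fewer than {self.min_cases} exposed cases"
            return result
        X = self._design()
        y = self.is_case.astype(float)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # separation, singular design, ...
            result.adjusted_reason = f"logistic fit failed: {exc}"
            return result
        result.converged = bool(fit.mle_retvals.get("converged", False))
        if not result.converged:
            result.adjusted_reason = "logistic fit did not converge"
            return result
        coef = fit.params["exposed"]
        se = fit.bse["exposed"]
        if not np.isfinite(coef) or not np.isfinite(se) or se > 1e3:
            result.adjusted_reason = "unstable exposure coefficient (separation?)"
            return result
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        result.adjusted = Estimate(
            math.exp(coef), math.exp(coef - z * se), math.exp(coef + z * se)
        )
        return result


def adjusted_ror(
    labels: Mapping[str, bool] | pd.Series,
    exposures: Mapping[str, FrozenSet[str]] | pd.Series,
    covariates: pd.DataFrame,
    index_drug: str,
    **kwargs,
) -> DisproportionalityResult:
    """Convenience wrapper: build the model from pipeline artefacts and fit.

    ``covariates`` is a DataFrame indexed by report_id with columns
    ``age_class`` and ``sex``.
    """
    labels = pd.Series(labels)
    exposures = pd.Series(exposures).reindex(labels.index)
    covariates = covariates.reindex(labels.index)
    if index_drug == TKI_CLASS:
        exposed = exposures.map(lambda s: len(s) > 0)
    else:
        exposed = exposures.map(lambda s: index_drug in s)
    model = CaseNonCaseModel(
        labels.astype(bool).to_numpy(),
        exposed.to_numpy(),
        covariates["age_class"].to_numpy(),
        covariates["sex"].to_numpy(),
        drug=index_drug,
        **kwargs,
    )
    return model.fit()


@dataclass
class ScreenInputs:
    """Pipeline artefacts feeding the full drug x SMQ screen.

    ``labels``: boolean DataFrame (report x SMQ); ``exposures``: Series
    of study-TKI sets per report (empty set = comparator anticancer
    report); ``covariates``: DataFrame with ``age_class`` and ``sex``.
    All three share the retained-report index.
    """

    labels: pd.DataFrame
    exposures: pd.Series
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if not (
            self.labels.index.equals(self.exposures.index)
            and self.labels.index.equals(self.covariates.index)
        ):
            raise ValueError("labels, exposures and covariates must share one index")


def screen_all(
    inputs: ScreenInputs,
    drugs: Sequence[str] = tuple(sorted(STUDY_TKIS)),
    include_class: bool = True,
    adjusted: bool = True,
    min_cases: int = 3,
) -> Tuple[List[DisproportionalityResult], List[DisproportionalityResult]]:
    """Run every (drug, SMQ) pair plus the pooled-class row per SMQ.

    Returns ``(eligible_results, ineligible)``: pairs with fewer than
    ``min_cases`` exposed cases are suppressed from the main list but
    reported separately with their counts.
    """
    drug_list = list(drugs) + ([TKI_CLASS] if include_class else [])
    tki_sets = inputs.exposures
    exposed_cols = {}
    for drug in drug_list:
        if drug == TKI_CLASS:
            exposed_cols[drug] = tki_sets.map(lambda s: len(s) > 0).to_numpy()
        else:
            exposed_cols[drug] = tki_sets.map(lambda s: drug in s).to_numpy()
    age = inputs.covariates["age_class"].to_numpy()
    sex = inputs.covariates["sex"].to_numpy()
    results: List[DisproportionalityResult] = []
    ineligible: List[DisproportionalityResult] = []
    for smq_name in inputs.labels.columns:
        y = inputs.labels[smq_name].to_numpy()
        for drug in drug_list:
            model = CaseNonCaseModel(
                y, exposed_cols[drug], age, sex, drug=drug, smq=smq_name, min_cases=min_cases
            )
            res = model.fit(adjusted=adjusted)
            (results if res.eligible else ineligible).append(res)
    return results, ineligible


def results_frame(results: Iterable[DisproportionalityResult]) -> pd.DataFrame:
    """Tabulate results for writing; one row per drug-SMQ pair."""
    return pd.DataFrame([r.as_dict() for r in results])
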