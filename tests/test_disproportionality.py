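"""Crude/adjusted ROR estimation, eligibility, SDR flags, full screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.disproportionality import (
    TKI_CLASS,
    CaseNonCaseModel,
    ContingencyTable,
    ScreenInputs,
    ZeroCellError,
    build_table,
    crude_ror,
    screen_all,
)

cells = st.integers(min_value=1, max_value=5000)


def test_symmetric_table_gives_unit_ror():
    est = crude_ror(ContingencyTable(10, 10, 10, 10))
    assert est.value == pytest.approx(1.0)
    assert est.ci_low * est.ci_high == pytest.approx(1.0)  # symmetric on log scale


def test_woolf_interval_frozen_example():
    # 2x2 with ROR 11; CI checked against an independent odds-ratio routine
    est = crude_ror(ContingencyTable(10, 90, 100, 9900))
    assert est.value == pytest.approx(11.0)
    assert est.ci_low == pytest.approx(5.5595846399431, rel=1e-9)
    assert est.ci_high == pytest.approx(21.764215824806325, rel=1e-9)


def test_class_level_qt_prolongation_table():
    # margins of the reference cohort: 269/3930 TKI and 846 comparator QT cases
    est = crude_ror(ContingencyTable(269, 24104, 846, 691944))
    assert est.value == pytest.approx(9.127750198313219, rel=1e-9)
    assert round(est.value, 1) == 9.1


def test_zero_cells_raise():
    with pytest.raises(ZeroCellError):
        crude_ror(ContingencyTable(5, 0, 10, 10))
    with pytest.raises(ZeroCellError):
        crude_ror(ContingencyTable(5, 10, 0, 10))


@settings(deadline=None, max_examples=200)
@given(cells, cells, cells, cells)
def test_swap_gives_reciprocal(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    assert crude_ror(t.swapped()).value == pytest.approx(1 / crude_ror(t).value)


@settings(deadline=None, max_examples=100)
@given(cells, cells, cells, cells)
def test_ror_strictly_increases_in_a(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    t2 = ContingencyTable(a + 1, b, c, d)
    assert crude_ror(t2).value > crude_ror(t).value


@settings(deadline=None, max_examples=60)
@given(cells, cells, cells, cells)
def test_matches_independent_oracle(a, b, c, d):
    import statsmodels.api as sm

    oracle = sm.stats.Table2x2([[a, b], [c, d]])
    est = crude_ror(ContingencyTable(a, b, c, d))
    lo, hi = oracle.oddsratio_confint()
    assert est.value == pytest.approx(oracle.oddsratio, rel=1e-9)
    assert est.ci_low == pytest.approx(lo, rel=1e-6)
    assert est.ci_high == pytest.approx(hi, rel=1e-6)


def test_build_table_partition():
    labels = pd.Series({"r1": True, "r2": False, "r3": True, "r4": False})
    exposures = pd.Series(
        {
            "r1": frozenset({"imatinib"}),
            "r2": frozenset({"imatinib", "nilotinib"}),
            "r3": frozenset(),
            "r4": frozenset(),
        }
    )
    t = build_table(labels, exposures, "imatinib")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
    # dual exposure lands in the index margin for either index drug
    t2 = build_table(labels, exposures, "nilotinib")
    assert (t2.a, t2.b) == (0, 1)
    t3 = build_table(labels, exposures, TKI_CLASS)
    assert (t3.a, t3.b, t3.c, t3.d) == (1, 1, 1, 1)


def test_build_table_empty_comparator_errors():
    labels = pd.Series({"r1": True})
    exposures = pd.Series({"r1": frozenset({"imatinib"})})
    with pytest.raises(ValueError, match="comparator"):
        build_table(labels, exposures, "imatinib")


def _simulate(n, p_exposed, or_true, rng, age_effect=0.0):
    exposed = rng.random(n) < p_exposed
    age = rng.choice(["26-50", "51-75"], size=n)
    eta = -2.0 + np.log(or_true) * exposed + age_effect * (age == "51-75")
    case = rng.random(n) < 1 / (1 + np.exp(-eta))
    sex = rng.choice(["female", "male"], size=n)
    return case, exposed, age, sex


def test_adjusted_equals_crude_with_constant_covariates():
    rng = np.random.default_rng(11)
    case, exposed, _, _ = _simulate(4000, 0.3, 2.5, rng)
    model = CaseNonCaseModel(
        case, exposed, np.repeat("51-75", 4000), np.repeat("male", 4000)
    )
    res = model.fit()
    assert res.adjusted.value == pytest.approx(res.crude.value, rel=1e-6)
    assert res.adjusted.ci_low == pytest.approx(res.crude.ci_low, rel=1e-4)


def test_null_exposure_ci_contains_one():
    rng = np.random.default_rng(12)
    case, exposed, age, sex = _simulate(20000, 0.3, 1.0, rng)
    res = CaseNonCaseModel(case, exposed, age, sex).fit()
    assert res.adjusted.ci_low < 1 < res.adjusted.ci_high
    assert not res.sdr


def test_adjusted_matches_sklearn_logistic():
    """Cross-check the exposure coefficient against an unpenalised GLM fit."""
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(13)
    case, exposed, age, sex = _simulate(5000, 0.4, 3.0, rng, age_effect=0.8)
    res = CaseNonCaseModel(case, exposed, age, sex).fit()
    X = np.column_stack(
        [exposed.astype(float), (age == "51-75").astype(float), (sex == "male").astype(float)]
    )
    skl = LogisticRegression(penalty=None, max_iter=5000, tol=1e-10).fit(X, case.astype(int))
    assert res.adjusted.value == pytest.approx(np.exp(skl.coef_[0][0]), rel=1e-4)


def test_eligibility_rule_suppresses_sparse_pairs():
    case = np.array([True] * 2 + [False] * 50 + [True] * 10 + [False] * 200)
    exposed = np.array([True] * 52 + [False] * 210)
    res = CaseNonCaseModel(case, exposed).fit()
    assert not res.eligible
    assert res.adjusted is None and "fewer than 3" in res.adjusted_reason
    assert not res.sdr


def test_separation_reported_not_crashed():
    # exposure perfectly predicts the outcome: no finite MLE exists
    case = np.array([True] * 20 + [False] * 80)
    exposed = case.copy()
    res = CaseNonCaseModel(case, exposed).fit()
    assert res.adjusted is None
    assert res.adjusted_reason


def test_screen_all_counts_and_class_rows():
    rng = np.random.default_rng(21)
    n = 4000
    drugs = ["imatinib", "dasatinib", "bosutinib", "nilotinib", "ponatinib"]
    assignment = rng.choice(drugs + ["other"] * 5, size=n)
    exposures = pd.Series(
        [frozenset({d}) if d != "other" else frozenset() for d in assignment],
        index=[f"r{i}" for i in range(n)],
    )
    labels = pd.DataFrame(
        {f"smq{j}": rng.random(n) < 0.3 for j in range(8)}, index=exposures.index
    )
    covariates = pd.DataFrame(
        {"age_class": rng.choice(["26-50", "51-75"], n), "sex": rng.choice(["female", "male"], n)},
        index=exposures.index,
    )
    inputs = ScreenInputs(labels=labels, exposures=exposures, covariates=covariates)
    results, ineligible = screen_all(inputs, drugs=drugs)
    assert len(results) + len(ineligible) == 48  # 5 drugs x 8 SMQs + 8 class rows
    assert len(results) == 48  # dense fixture: every pair eligible
    assert {r.drug for r in results} == set(drugs) | {TKI_CLASS}


def test_summary_is_printable():
    res = CaseNonCaseModel(
        np.array([True] * 30 + [False] * 70 + [True] * 10 + [False] * 90),
        np.array([True] * 100 + [False] * 100),
    ).fit()
    text = res.summary()
    assert "crude ROR" in text and "adjusted ROR" in text and "SDR" in text
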