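"""Contingency/chi-squared and adjusted-OR regression against independent oracles."""
import numpy as np
import pandas as pd
import pytest

from famhist import association
from famhist.association import (
    ContingencyTable,
    build_contingency,
    chi_squared,
    fit_logistic,
    report_ors,
)
from famhist.merge import build_patient_table
from famhist.types import AdmissionNote, FamilyHistoryLabel
from helpers import newton_logistic as _newton_logistic, simulate_patients as _patients_df




# -------------------------------------------------------------- contingency
def test_build_contingency_hand_count():
    notes = []
    labels = {}
    specs = [("p1", "F32", 1), ("p2", "F31", 1), ("p3", "F32", 0), ("p4", "F33", 0)]
    for pid, diag, fh in specs:
        notes.append(
            AdmissionNote(
                note_id=f"n{pid}", patient_id=pid, admission_year=2015, age_years=50,
                gender="male", marital_status="married", profession="retiree",
                first_diagnosis=diag, text="家族史无特殊。",
            )
        )
        labels[f"n{pid}"] = FamilyHistoryLabel((fh, 0, 0, 0, 0))
    table = build_contingency(build_patient_table(notes, labels))
    idx = {r: i for i, r in enumerate(table.row_labels)}
    cols = {c: j for j, c in enumerate(table.col_labels)}
    assert table.counts[idx["1"], cols["MDD"]] == 1
    assert table.counts[idx["1"], cols["BD"]] == 1
    assert table.counts[idx["0"], cols["MDD"]] == 2
    assert table.counts[idx["0"], cols["BD"]] == 0
    assert table.col_margins.tolist() == [1, 3]  # BD, MDD group sizes


def test_build_contingency_empty_cohort_and_indicator_rows():
    empty = build_contingency(pd.DataFrame(columns=["any_family_history", "diagnosis_group"]))
    assert empty.counts.size == 0
    rng = np.random.default_rng(0)
    df = _patients_df(200, rng)
    tab = build_contingency(df, row_spec=["fh_F20", "fh_F32"])
    assert tab.overlapping_rows
    assert tab.counts[0].sum() == df["fh_F20"].sum()


def test_build_contingency_unknown_field():
    with pytest.raises(KeyError, match="nope"):
        build_contingency(_patients_df(10, np.random.default_rng(0)), row_spec="nope")


def test_chi_squared_closed_form_2x2():
    # n (ad - bc)^2 / (r1 r2 c1 c2) = 60 * (100-400)^2 / 30^4 = 6.6667
    table = ContingencyTable(["a", "b"], ["x", "y"], np.array([[10, 20], [20, 10]]))
    stat, df, p = chi_squared(table)
    assert stat == pytest.approx(60 * (10 * 10 - 20 * 20) ** 2 / 30**4)
    assert stat == pytest.approx(6.66667, abs=1e-4)
    assert df == 1


def test_chi_squared_independence_gives_zero():
    table = ContingencyTable(["a", "b"], ["x", "y"], np.array([[10, 20], [20, 40]]))
    stat, _, p = chi_squared(table)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_squared_matches_scipy_on_random_tables():
    from scipy.stats import chi2_contingency

    rng = np.random.default_rng(5)
    for _ in range(30):
        counts = rng.integers(1, 60, size=(5, 3))
        table = ContingencyTable([str(i) for i in range(5)], list("abc"), counts)
        stat, df, p = chi_squared(table)
        ref = chi2_contingency(counts, correction=False)
        assert stat == pytest.approx(float(ref.statistic), abs=1e-9)
        assert df == int(ref.dof)
        assert p == pytest.approx(float(ref.pvalue), abs=1e-9)


def test_chi_squared_degenerate_margin():
    table = ContingencyTable(["a", "b"], ["x", "y"], np.array([[0, 0], [5, 5]]))
    with pytest.raises(ValueError, match="margin"):
        chi_squared(table)


# ----------------------------------------------------------------- logistic


def test_fit_logistic_matches_newton_oracle():
    rng = np.random.default_rng(11)
    df = _patients_df(600, rng, beta=[-1.0, 0.2, 0.0, -0.5, 0.4])
    res = fit_logistic(df, stepwise="none", candidate_terms=())
    X = df[[f"fh_{c}" for c in ("F20", "F32", "F31", "F28", "F29")]].to_numpy(float)
    y = (df["diagnosis_group"] == "MDD").astype(int).to_numpy()
    beta, se = _newton_logistic(y, X)
    for i, name in enumerate(association.FH_COLUMNS):
        t = res.term(name)
        assert t.coef == pytest.approx(beta[i + 1], abs=1e-6)
        assert t.se == pytest.approx(se[i + 1], abs=1e-6)
        assert t.odds_ratio == pytest.approx(np.exp(beta[i + 1]), rel=1e-6)


def test_null_exposure_gives_or_near_one_with_ci_covering_one():
    # under a null exposure the CI covers OR = 1 about 95% of the time and
    # the estimates centre on 1
    coefs, covering = [], 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        df = _patients_df(2000, rng, beta=np.zeros(5))
        res = fit_logistic(df, stepwise="none", candidate_terms=())
        t = res.term("fh_F20")
        coefs.append(t.coef)
        covering += int(t.ci_low < 1.0 < t.ci_high)
    assert covering >= 16
    assert abs(np.mean(coefs)) < 0.15


def test_protective_or_recovered_within_own_ci():
    # configured truth OR = 0.137 for one forced indicator, null demographics;
    # the estimate's own 95% CI covers the truth in >= 90% of 50 seeds
    true_or = 0.137
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        df = _patients_df(
            20000, rng, beta=[np.log(true_or), 0, 0, 0, 0],
            prevalence=[0.02, 0.08, 0.05, 0.08, 0.05],
        )
        res = fit_logistic(df, stepwise="none", candidate_terms=())
        t = res.term("fh_F20")
        if t.ci_low <= true_or <= t.ci_high:
            hits += 1
    assert hits >= 45


def test_coefficient_bias_shrinks_with_sample_size():
    beta_true = np.log(0.464)
    biases = {}
    for n in (2000, 20000):
        errs = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            df = _patients_df(n, rng, beta=[beta_true, 0, 0, 0, 0])
            res = fit_logistic(df, stepwise="none", candidate_terms=())
            errs.append(res.term("fh_F20").coef - beta_true)
        biases[n] = abs(float(np.mean(errs)))
    assert biases[20000] < 0.05
    assert biases[20000] <= biases[2000] + 0.02


def test_stepwise_keeps_forced_terms_and_selects_informative_covariate():
    rng = np.random.default_rng(8)
    df = _patients_df(3000, rng, beta=[-0.8, 0, 0, 0, 0])
    # make age genuinely predictive
    logit = 0.03 * (df["age_years"] - 50)
    flip = rng.random(len(df)) < 1 / (1 + np.exp(-logit))
    df["diagnosis_group"] = np.where(flip, "MDD", df["diagnosis_group"])
    res = fit_logistic(df)
    names = [t.name for t in res.terms]
    for col in association.FH_COLUMNS:
        assert col in names  # forced terms always present
    assert "age_years" in res.included_covariates


def test_single_class_outcome_errors():
    df = _patients_df(50, np.random.default_rng(0))
    df["diagnosis_group"] = "MDD"
    with pytest.raises(ValueError, match="single class"):
        fit_logistic(df)


def test_report_ors_formats_reference_rows():
    rng = np.random.default_rng(3)
    df = _patients_df(1500, rng, beta=[np.log(2.0), 0, 0, 0, 0])
    res = fit_logistic(df, candidate_terms=("marital_status",), stepwise="none")
    text = report_ors(res)
    assert "1.00" in text and "(ref.)" in text
    t = res.term("fh_F20")
    assert f"{t.odds_ratio:.3f}" in text
    res.converged = False
    with pytest.raises(ValueError, match="converge"):
        report_ors(res)
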