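"""Age-centered group-contrast OLS: estimates, predictions, invariants."""

import numpy as np
import pandas as pd
import pytest

import ablelife as al
from ablelife.regression import RegressionResult, TERMS, fit_group_regression, predict_expected_years


def _frame(sexes, races, ages, y):
    return pd.DataFrame(
        {
            "person_id": np.arange(len(y)),
            "sex": sexes,
            "race": races,
            "age_band": "70-74",
            "baseline_age": ages,
            "yol": y,
            "yhl": y,
            "yal": y,
        }
    )


def _random_cohort(rng, n=400, beta=None):
    beta = beta or {"intercept": 12.0, "age": -0.4,
                    "white_male": -1.7, "non_white_female": -0.3, "non_white_male": -2.6}
    groups = [("F", "white"), ("M", "white"), ("F", "non-white"), ("M", "non-white")]
    gi = rng.integers(0, 4, n)
    sexes = np.array([groups[i][0] for i in gi])
    races = np.array([groups[i][1] for i in gi])
    ages = rng.integers(65, 90, n).astype(float)
    offsets = np.array(
        [0.0, beta["white_male"], beta["non_white_female"], beta["non_white_male"]]
    )[gi]
    y = beta["intercept"] + beta["age"] * (ages - 73.0) + offsets + rng.normal(0, 2.0, n)
    return _frame(sexes, races, ages, y), beta


def test_constant_response_recovers_constant():
    rng = np.random.default_rng(0)
    df, _ = _random_cohort(rng)
    df["yol"] = 7.25
    res = fit_group_regression(df, "yol")
    assert res.coef["intercept"] == pytest.approx(7.25, abs=1e-9)
    for term in ("age", "white_male", "non_white_female", "non_white_male"):
        assert res.coef[term] == pytest.approx(0.0, abs=1e-9)


def test_six_row_hand_computed_normal_equations():
    """Coefficients agree with an explicit (X'X)^{-1} X'y solution."""
    df = _frame(
        sexes=["F", "F", "M", "M", "F", "M"],
        races=["white", "white", "white", "white", "non-white", "non-white"],
        ages=[70.0, 76.0, 71.0, 80.0, 73.0, 69.0],
        y=[14.0, 10.5, 11.0, 6.5, 12.0, 9.0],
    )
    res = fit_group_regression(df, "yol", centering_age=73.0)
    X = np.column_stack(
        [
            np.ones(6),
            np.array([70, 76, 71, 80, 73, 69], dtype=float) - 73.0,
            [0, 0, 1, 1, 0, 0],
            [0, 0, 0, 0, 1, 0],
            [0, 0, 0, 0, 0, 1],
        ]
    )
    y = np.array([14.0, 10.5, 11.0, 6.5, 12.0, 9.0])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    for term, b in zip(TERMS, beta):
        assert res.coef[term] == pytest.approx(b, abs=1e-10)


def test_residual_orthogonality():
    rng = np.random.default_rng(1)
    df, _ = _random_cohort(rng)
    res = fit_group_regression(df, "yol")
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["baseline_age"] - 73.0,
            ((df["sex"] == "M") & (df["race"] == "white")).astype(float),
            ((df["sex"] == "F") & (df["race"] == "non-white")).astype(float),
            ((df["sex"] == "M") & (df["race"] == "non-white")).astype(float),
        ]
    )
    beta = np.array([res.coef[t] for t in TERMS])
    resid = df["yol"].to_numpy() - X @ beta
    assert np.max(np.abs(X.T @ resid)) < 1e-8 * len(df)


def test_centering_change_shifts_only_intercept():
    rng = np.random.default_rng(2)
    df, _ = _random_cohort(rng)
    a = fit_group_regression(df, "yol", centering_age=73.0)
    b = fit_group_regression(df, "yol", centering_age=78.0)
    assert b.coef["intercept"] == pytest.approx(a.coef["intercept"] + a.coef["age"] * 5.0)
    for term in ("age", "white_male", "non_white_female", "non_white_male"):
        assert b.coef[term] == pytest.approx(a.coef[term])
        assert b.p_values[term] == pytest.approx(a.p_values[term])


def test_single_cohort_parameter_recovery_within_ci():
    rng = np.random.default_rng(4)
    df, beta = _random_cohort(rng, n=2000)
    res = fit_group_regression(df, "yol")
    for term, true in beta.items():
        assert res.ci_low[term] <= true <= res.ci_high[term], term


def test_prediction_reference_group_at_centering_age():
    res = RegressionResult.from_coefficients("yol", intercept=12.5, age=-0.4, white_male=-1.5)
    assert predict_expected_years(res, "F", "white", 73.0) == 12.5
    assert predict_expected_years(res, "M", "white", 73.0) == pytest.approx(11.0)
    assert predict_expected_years(res, "F", "white", 75.0) == pytest.approx(12.5 - 0.8)


def test_prediction_group_validation():
    res = RegressionResult(outcome="yol", centering_age=73.0, coef={"intercept": 10.0, "age": 0.0})
    with pytest.raises(ValueError, match="unknown group"):
        predict_expected_years(res, "X", "white", 73.0)
    with pytest.raises(ValueError, match="not among the fitted groups"):
        predict_expected_years(res, "M", "white", 73.0)


def test_missing_group_gets_no_coefficient():
    rng = np.random.default_rng(5)
    df, _ = _random_cohort(rng)
    df = df[df["race"] == "white"].reset_index(drop=True)
    res = fit_group_regression(df, "yol")
    assert "non_white_female" not in res.coef
    assert "non_white_male" not in res.coef


def test_rank_deficiency_names_column():
    rng = np.random.default_rng(6)
    df, _ = _random_cohort(rng)
    df["baseline_age"] = 73.0  # age column becomes all zeros
    with pytest.raises(ValueError, match="age"):
        fit_group_regression(df, "yol")


def test_prediction_matches_age_adjusted_group_means():
    """Two-step check: regress out age, then compare group means of the
    age-adjusted outcome with the model predictions at the centering age."""
    rng = np.random.default_rng(9)
    df, _ = _random_cohort(rng, n=3000)
    res = fit_group_regression(df, "yol")
    adj = df["yol"] - res.coef["age"] * (df["baseline_age"] - 73.0)
    for (sex, race), term in [
        (("F", "white"), None),
        (("M", "white"), "white_male"),
        (("F", "non-white"), "non_white_female"),
        (("M", "non-white"), "non_white_male"),
    ]:
        sel = (df["sex"] == sex) & (df["race"] == race)
        pred = predict_expected_years(res, sex, race, 73.0)
        # exact by the normal equations: group-dummy residuals sum to zero
        assert adj[sel].mean() == pytest.approx(pred, abs=1e-8)


def test_linearity_diagnostic_reports_r2():
    rng = np.random.default_rng(10)
    df, _ = _random_cohort(rng, n=1500)
    diag = al.linearity_diagnostic(df, "yol")
    assert 0.0 <= diag["r2_linear"] <= diag["r2_spline"] <= 1.0
    assert diag["r2_gain"] < 0.01  # the generating model is linear in age


def test_result_table_shape():
    rng = np.random.default_rng(11)
    df, _ = _random_cohort(rng)
    res = fit_group_regression(df, "yhl")
    table = res.to_frame()
    assert list(table.columns) == ["outcome", "term", "estimate", "ci_low", "ci_high", "p_value"]
    assert list(table["term"]) == list(TERMS)
    assert ((table["ci_low"] <= table["estimate"]) & (table["estimate"] <= table["ci_high"])).all()
    assert table["p_value"].between(0, 1).all()
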