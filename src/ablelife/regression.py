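"""Age-centered group-contrast linear models for YOL, YHL, and YAL.

The model regresses an outcome on baseline age, entered linearly and
centered at a reference age (default 73, a typical cohort mean), plus
indicator contrasts for the sex-race groups with white females as the
reference. The intercept is then directly the expected years for a white
female at the centering age, and each group coefficient the difference in
expected years for that group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Model terms in reporting order; white female is the reference group.
TERMS = ("intercept", "age", "white_male", "non_white_female", "non_white_male")

_GROUP_TERM = {
    ("F", "white"): None,
    ("M", "white"): "white_male",
    ("F", "non-white"): "non_white_female",
    ("M", "non-white"): "non_white_male",
}


@dataclass
class RegressionResult:
    """Coefficient table of one fitted (or published) group-contrast model."""

    outcome: str
    centering_age: float
    coef: dict
    ci_low: dict = field(default_factory=dict)
    ci_high: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    n: Optional[int] = None

    @classmethod
    def from_coefficients(
        cls,
        outcome: str,
        intercept: float,
        age: float = 0.0,
        white_male: float = 0.0,
        non_white_female: float = 0.0,
        non_white_male: float = 0.0,
        centering_age: float = 73.0,
    ) -> "RegressionResult":
        """Build a result from an externally reported coefficient table."""
        return cls(
            outcome=outcome,
            centering_age=centering_age,
            coef={
                "intercept": intercept,
                "age": age,
                "white_male": white_male,
                "non_white_female": non_white_female,
                "non_white_male": non_white_male,
            },
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term in TERMS:
            if term not in self.coef:
                continue
            rows.append(
                {
                    "outcome": self.outcome,
                    "term": term,
                    "estimate": self.coef[term],
                    "ci_low": self.ci_low.get(term, np.nan),
                    "ci_high": self.ci_high.get(term, np.nan),
                    "p_value": self.p_values.get(term, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _design(person_years: pd.DataFrame, centering_age: float) -> pd.DataFrame:
    X = pd.DataFrame(index=person_years.index)
    X["intercept"] = 1.0
    X["age"] = person_years["baseline_age"].astype(float) - centering_age
    for (sex, race), term in _GROUP_TERM.items():
        if term is not None:
            X[term] = (
                (person_years["sex"] == sex) & (person_years["race"] == race)
            ).astype(float)
    return X


def fit_group_regression(
    person_years: pd.DataFrame,
    outcome: str,
    centering_age: float = 73.0,
) -> RegressionResult:
    """Ordinary least squares of the outcome on centered age and group.

    Groups absent from the data have their column dropped (they get no
    coefficient); a present-but-collinear design raises an error naming
    the deficient column. CIs use the t distribution with n - p degrees of
    freedom, p-values are two-tailed.
    """
    if outcome not in ("yol", "yhl", "yal"):
        raise ValueError(f"unknown outcome {outcome!r}")
    X = _design(person_years, centering_age)
    # groups with no members cannot be estimated
    X = X.loc[:, [c for c in X.columns if c in ("intercept", "age") or X[c].any()]]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} observations to fit {p} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # identify a column whose removal restores full rank
        for c in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank:
                raise ValueError(f"design matrix is rank deficient in column {c!r}")
        raise ValueError("design matrix is rank deficient")
    y = person_years[outcome].astype(float)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        outcome=outcome,
        centering_age=centering_age,
        coef=dict(fit.params),
        ci_low=dict(ci[0]),
        ci_high=dict(ci[1]),
        p_values=dict(fit.pvalues),
        n=n,
    )


def predict_expected_years(
    result: RegressionResult,
    sex: str,
    race: str,
    age: float,
) -> float:
    """Expected years for a group member of the given age.

    intercept + age_slope * (age - centering_age) + group offset (zero for
    the white-female reference). Round to one decimal when reporting.
    """
    try:
        term = _GROUP_TERM[(sex, race)]
    except KeyError:
        raise ValueError(f"unknown group {(sex, race)!r}") from None
    value = result.coef["intercept"] + result.coef.get("age", 0.0) * (
        age - result.centering_age
    )
    if term is not None:
        if term not in result.coef:
            raise ValueError(f"group {(sex, race)!r} was not among the fitted groups")
        value += result.coef[term]
    return float(value)


def linearity_diagnostic(
    person_years: pd.DataFrame,
    outcome: str,
    centering_age: float = 73.0,
    knots: tuple = (70.0, 75.0, 80.0),
) -> dict:
    """Compare the linear-age fit against a linear-spline-age fit.

    Returns both R² values and their difference. A small difference
    supports modelling age linearly; this is an optional diagnostic, not a
    gate on fitting.
    """
    base = _design(person_years, centering_age)
    lin_fit = sm.OLS(person_years[outcome].astype(float), base).fit()
    spline = base.copy()
    age = person_years["baseline_age"].astype(float)
    for k in knots:
        spline[f"age_gt_{k:g}"] = np.maximum(age - k, 0.0)
    spl_fit = sm.OLS(person_years[outcome].astype(float), spline).fit()
    return {
        "r2_linear": float(lin_fit.rsquared),
        "r2_spline": float(spl_fit.rsquared),
        "r2_gain": float(spl_fit.rsquared - lin_fit.rsquared),
    }
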