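"""Epigenetic age acceleration and covariate-adjusted inference.

Implements the study-level statistical layer: the age-adjusted epigenetic
age residual, cross-sectional general linear models with planned covariates,
change-score models for the longitudinal sample, and the
missing-completely-at-random checks comparing retained vs. non-retained
subjects at baseline.

Sex is coded as a binary indicator (F = 0, M = 1) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CollinearityError, DegenerateDesignError, InvalidSpecError

__all__ = [
    "GLMResult",
    "LongitudinalResult",
    "age_accel",
    "fit_glm",
    "longitudinal_model",
    "missingness_tests",
    "encode_sex",
]

SEX_CODING = {"F": 0.0, "M": 1.0}


def encode_sex(sex: Sequence) -> np.ndarray:
    """Binary sex indicator (F = 0, M = 1); numeric input passes through."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "OUS":
        try:
            return np.array([SEX_CODING[str(s)] for s in arr])
        except KeyError as exc:
            raise InvalidSpecError(f"unknown sex code {exc}") from exc
    return arr.astype(float)


@dataclass
class GLMResult:
    """OLS fit summary: one row of statistics per design term."""

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    df_residual: int
    n: int
    term_of_interest: str | None = None

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        return {
            "coef": float(self.coefficients[i]),
            "se": float(self.standard_errors[i]),
            "t": float(self.t_statistics[i]),
            "p": float(self.p_values[i]),
            "df": self.df_residual,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "estimate": self.coefficients,
            "se": self.standard_errors,
            "t": self.t_statistics,
            "df": self.df_residual,
            "p": self.p_values,
        })


@dataclass
class LongitudinalResult:
    """Change-score model F-test for one term (1 numerator df)."""

    term: str
    F_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float
    estimate: float

    def __post_init__(self) -> None:
        if self.F_statistic < 0:
            raise InvalidSpecError("F statistic must be non-negative")


def age_accel(grimage: Sequence[float], age: Sequence[float]) -> np.ndarray:
    """Age-adjusted epigenetic age: OLS residuals of GrimAge on age.

    Residuals have mean zero and zero sample correlation with age; a positive
    value means accelerated mortality risk relative to chronological age.
    """
    g = np.asarray(grimage, dtype=float)
    a = np.asarray(age, dtype=float)
    if g.shape != a.shape or g.ndim != 1 or g.size < 3:
        raise InvalidSpecError("grimage and age must be equal-length vectors, n >= 3")
    if np.ptp(a) < 1e-12:
        raise DegenerateDesignError("age is constant; regression is degenerate")
    x = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(x, g, rcond=None)
    return g - x @ beta


def _design_matrix(covariates: Mapping[str, Sequence[float]],
                   n: int) -> tuple[np.ndarray, list[str]]:
    names = ["intercept"]
    cols = [np.ones(n)]
    for name, values in covariates.items():
        v = encode_sex(values) if name == "sex" else np.asarray(values, dtype=float)
        if v.shape != (n,):
            raise InvalidSpecError(f"covariate {name!r} has wrong length")
        names.append(name)
        cols.append(v)
    return np.column_stack(cols), names


def _find_collinear(x: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    rank = np.linalg.matrix_rank(x)
    for j in range(x.shape[1]):
        keep = [k for k in range(x.shape[1]) if k != j]
        if np.linalg.matrix_rank(x[:, keep]) == rank:
            bad.append(names[j])
    return bad or names


def fit_glm(response: Sequence[float],
            covariates: Mapping[str, Sequence[float]],
            term_of_interest: str | None = None) -> GLMResult:
    """OLS with intercept; two-sided t-tests for every term.

    ``covariates`` maps term name to values; a term named ``"sex"`` may hold
    ``"M"``/``"F"`` labels and is binary coded.  Raises
    :class:`CollinearityError` (naming the offending terms) on a
    rank-deficient design.
    """
    y = np.asarray(response, dtype=float)
    n = y.size
    x, names = _design_matrix(covariates, n)
    if term_of_interest is not None and term_of_interest not in names:
        raise InvalidSpecError(f"unknown term of interest {term_of_interest!r}")
    if n <= x.shape[1]:
        raise DegenerateDesignError(
            f"n={n} does not exceed the {x.shape[1]} design terms")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearityError(_find_collinear(x, names))

    import statsmodels.api as sm

    fit = sm.OLS(y, x).fit()
    return GLMResult(
        terms=names,
        coefficients=np.asarray(fit.params),
        standard_errors=np.asarray(fit.bse),
        t_statistics=np.asarray(fit.tvalues),
        p_values=np.asarray(fit.pvalues),
        df_residual=int(fit.df_resid),
        n=n,
        term_of_interest=term_of_interest,
    )


def longitudinal_model(y_baseline: Sequence[float],
                       y_followup: Sequence[float],
                       covariates: Mapping[str, Sequence[float]],
                       term_of_interest: str | None = None
                       ) -> LongitudinalResult:
    """Within-subject change model with between-subject controls.

    Realized as change-score ANCOVA: ``y_followup - y_baseline`` is regressed
    on an intercept, the term of interest (if any) and the covariates; the
    reported F (1 numerator df) is the squared t of the term of interest, or
    of the intercept when no term is given (testing mean change over time).
    Only complete pairs may be passed in (listwise deletion upstream).
    """
    yb = np.asarray(y_baseline, dtype=float)
    yf = np.asarray(y_followup, dtype=float)
    if yb.shape != yf.shape or yb.ndim != 1:
        raise InvalidSpecError("baseline/followup must be equal-length vectors")
    if np.any(~np.isfinite(yb)) or np.any(~np.isfinite(yf)):
        raise InvalidSpecError("longitudinal model requires complete pairs")
    if yb.size == 0:
        raise DegenerateDesignError("no complete pairs")
    dy = yf - yb
    n = dy.size
    if n < len(covariates) + (2 if term_of_interest else 1) + 1:
        raise DegenerateDesignError("too few complete pairs for the model")
    glm = fit_glm(dy, covariates, term_of_interest)
    term = term_of_interest or "intercept"
    row = glm[term]
    f = row["t"] ** 2
    if not np.isfinite(f):
        # zero residual variance: an exact fit gives 0/0
        f = 0.0 if abs(row["coef"]) < 1e-12 else np.inf
    p = float(sps.f.sf(f, 1, glm.df_residual)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return LongitudinalResult(
        term=term, F_statistic=float(f), df_numerator=1,
        df_denominator=glm.df_residual, p_value=p, estimate=row["coef"],
    )


_MISSINGNESS_VARS = ("age_years", "sex", "total_brain_volume", "wmh_volume",
                     "grimage_years", "age_accel_grim")


def missingness_tests(cohort: pd.DataFrame,
                      variables: Sequence[str] = _MISSINGNESS_VARS
                      ) -> pd.DataFrame:
    """Pooled-variance two-sample t-tests of retained vs. non-retained.

    Tests whether follow-up dropout relates to each baseline variable (the
    missing-completely-at-random check).  Returns a tidy frame with columns
    ``variable, t_statistic, df, p``; groups smaller than 2 yield NaN rows.
    """
    base = cohort[cohort["timepoint"] == "baseline"]
    retained = base["retained_at_followup"].astype(bool).to_numpy()
    if retained.all() or (~retained).all():
        raise InvalidSpecError("both retained and non-retained groups required")
    rows = []
    for var in variables:
        vals = encode_sex(base[var]) if var == "sex" else base[var].to_numpy(float)
        a, b = vals[retained], vals[~retained]
        if a.size < 2 or b.size < 2:
            rows.append({"variable": var, "t_statistic": np.nan,
                         "df": np.nan, "p": np.nan})
            continue
        t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append({"variable": var, "t_statistic": float(t),
                     "df": a.size + b.size - 2, "p": float(p)})
    return pd.DataFrame(rows)
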