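"""Pathology composites, global cognition, and the residual-cognition trait.

Residual cognition is the residual of global cognitive performance
proximate to death from a multivariate linear model on four demographic
covariates (age at death, sex, education, cohort) and ten neuropathology
indices.  It is the dependent trait of every downstream omic association.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import DEMOGRAPHIC_COLUMNS, PATHOLOGY_COLUMNS

__all__ = [
    "composite_pathology_score",
    "caa_score",
    "global_cognition",
    "decline_slope",
    "ResidualCognition",
    "compute_residual_cognition",
]


def composite_pathology_score(regional_scaled_counts) -> float:
    """Square root of the mean of per-region scaled pathology counts.

    The regional counts are expected to be scaled (divided by a baseline
    SD) without centering, so they are nonnegative and the square root of
    their average is defined.
    """
    vals = np.asarray(regional_scaled_counts, dtype=float)
    if vals.size == 0:
        raise ValueError("at least one regional value is required")
    if (vals < 0).any():
        raise ValueError("regional scaled counts must be nonnegative")
    return float(np.sqrt(vals.mean()))


def caa_score(regional_grades) -> float:
    """Mean of the four neocortical cerebral-amyloid-angiopathy grades (0-4)."""
    grades = np.asarray(regional_grades, dtype=float)
    if grades.shape != (4,):
        raise ValueError("exactly four regional grades are required")
    if (grades < 0).any() or (grades > 4).any():
        raise ValueError("grades must lie in [0, 4]")
    return float(grades.mean())


def global_cognition(
    test_scores,
    baseline_means,
    baseline_sds,
    min_fraction_present: float = 0.5,
) -> float:
    """Mean of per-test z-scores (baseline mean/SD normalisation).

    Missing tests (NaN) are tolerated as long as at least
    ``min_fraction_present`` of the battery is observed.
    """
    scores = np.asarray(test_scores, dtype=float)
    means = np.asarray(baseline_means, dtype=float)
    sds = np.asarray(baseline_sds, dtype=float)
    if (sds <= 0).any():
        raise ValueError("baseline SDs must be positive")
    present = ~np.isnan(scores)
    if not present.any():
        raise ValueError("all tests missing")
    if present.mean() < min_fraction_present:
        raise ValueError(
            f"only {present.sum()}/{scores.size} tests present "
            f"(minimum fraction {min_fraction_present})"
        )
    z = (scores[present] - means[present]) / sds[present]
    return float(z.mean())


def decline_slope(visit_times, global_scores) -> float:
    """Per-subject least-squares slope of global cognition on time (per year).

    Returns NaN when fewer than three visits are available.
    """
    t = np.asarray(visit_times, dtype=float)
    y = np.asarray(global_scores, dtype=float)
    ok = ~(np.isnan(t) | np.isnan(y))
    t, y = t[ok], y[ok]
    if t.size < 3:
        return float("nan")
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0:
        raise ValueError("visit times are constant")
    return float((tc @ (y - y.mean())) / denom)


class ResidualCognition(RegressorMixin, BaseEstimator):
    """Linear model of cognition on demographics + pathologies; the residual
    is the "residual cognition" trait.

    Parameters
    ----------
    demographic_columns, pathology_columns : list of str
        Covariate columns taken from the two input tables.  Defaults are
        the four demographics and ten pathology indices.
    min_cases : int
        Minimum number of complete cases required to fit.

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : fitted coefficients
    residuals_ : pd.Series of residuals indexed by subject_id (complete cases)
    r_squared_, adjusted_r_squared_, n_ : fit statistics
    feature_names_in_ : covariate column order
    """

    def __init__(
        self,
        demographic_columns: list[str] | None = None,
        pathology_columns: list[str] | None = None,
        min_cases: int = 20,
    ):
        self.demographic_columns = demographic_columns
        self.pathology_columns = pathology_columns
        self.min_cases = min_cases

    def _columns(self) -> list[str]:
        demo = self.demographic_columns or DEMOGRAPHIC_COLUMNS
        path = self.pathology_columns or PATHOLOGY_COLUMNS
        return list(demo) + list(path)

    def _design(self, subjects: pd.DataFrame, pathologies: pd.DataFrame) -> pd.DataFrame:
        merged = subjects.merge(pathologies, on="subject_id", how="inner", validate="1:1")
        merged = merged.set_index("subject_id")
        cols = self._columns()
        missing = [c for c in cols if c not in merged.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        X = merged[cols].apply(pd.to_numeric, errors="coerce")
        return X

    def fit(self, subjects: pd.DataFrame, pathologies: pd.DataFrame, y=None):
        """Fit on complete cases of the merged subject/pathology tables.

        ``y`` defaults to the ``last_global_cognition`` column of
        ``subjects``.
        """
        X = self._design(subjects, pathologies)
        if y is None:
            yv = subjects.set_index("subject_id")["last_global_cognition"]
        else:
            yv = pd.Series(np.asarray(y, float), index=X.index)
        yv = pd.to_numeric(yv.reindex(X.index), errors="coerce")
        complete = X.notna().all(axis=1) & yv.notna()
        X, yv = X[complete], yv[complete]
        n = len(X)
        if n < self.min_cases:
            raise ValueError(f"only {n} complete cases (minimum {self.min_cases})")
        A = np.column_stack([np.ones(n), X.to_numpy(float)])
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            # name the offending columns for the error message
            bad = []
            base = np.ones((n, 1))
            for j, col in enumerate(X.columns):
                cand = np.column_stack([base, X.iloc[:, j].to_numpy(float)])
                if np.linalg.matrix_rank(cand) == base.shape[1]:
                    bad.append(col)
                else:
                    base = cand
            raise ValueError(f"rank-deficient design; collinear columns: {bad or 'unknown'}")
        coefs, _, _, _ = np.linalg.lstsq(A, yv.to_numpy(float), rcond=None)
        fitted = A @ coefs
        resid = yv.to_numpy(float) - fitted
        ss_res = float(resid @ resid)
        yc = yv.to_numpy(float) - yv.mean()
        ss_tot = float(yc @ yc)
        p = X.shape[1]
        self.intercept_ = float(coefs[0])
        self.coef_ = coefs[1:]
        self.feature_names_in_ = list(X.columns)
        self.residuals_ = pd.Series(resid, index=X.index, name="residual_cognition")
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.adjusted_r_squared_ = 1.0 - (1.0 - self.r_squared_) * (n - 1) / (n - p - 1)
        self.n_ = n
        return self

    def predict(self, subjects: pd.DataFrame, pathologies: pd.DataFrame) -> pd.Series:
        X = self._design(subjects, pathologies)
        vals = self.intercept_ + X.to_numpy(float) @ self.coef_
        return pd.Series(vals, index=X.index, name="predicted_cognition")


def compute_residual_cognition(
    subjects: pd.DataFrame, pathologies: pd.DataFrame, **kwargs
) -> tuple[pd.DataFrame, ResidualCognition]:
    """Fit the residual-cognition model and write residuals back.

    Returns a copy of ``subjects`` with a ``residual_cognition`` column
    (NaN for incomplete cases) together with the fitted model.
    """
    model = ResidualCognition(**kwargs).fit(subjects, pathologies)
    out = subjects.copy()
    out["residual_cognition"] = out["subject_id"].map(model.residuals_)
    return out, model
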