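"""Sequential adjusted-R² ledger for last global cognition.

Two nested OLS models of the raw last global cognitive score are
compared: a base model on demographics + the ten pathologies, and a full
model that adds the candidate genes' lead-SNP dosages, top-CpG beta
values and RNA levels.  The gain in adjusted R² is the variance increment
attributable to the molecular features; 1 - full adjusted R² is the
unexplained share.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import DEMOGRAPHIC_COLUMNS, PATHOLOGY_COLUMNS, VarianceLedger

__all__ = ["adjusted_r2", "SequentialVariancePartition", "sequential_ledger"]


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R²)(n - 1)/(n - p - 1); requires n > p + 1."""
    if n <= p + 1:
        raise ValueError(f"n={n} must exceed p+1={p + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _ols_r2(X: np.ndarray, y: np.ndarray, names: list[str]) -> float:
    A = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        bad = []
        base = np.ones((len(y), 1))
        for j, nm in enumerate(names):
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(nm)
            else:
                base = cand
        raise ValueError(f"rank-deficient design; collinear columns: {bad or 'unknown'}")
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    yc = y - y.mean()
    sst = float(yc @ yc)
    return 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0


class SequentialVariancePartition(BaseEstimator):
    """Nested-model adjusted-R² comparison.

    Parameters
    ----------
    demographic_columns, pathology_columns : base-model covariates.

    Attributes (after fit)
    ----------------------
    ledger_ : VarianceLedger with base/full (adjusted) R², increment and
        unexplained share over the complete-case subset.
    """

    def __init__(self, demographic_columns=None, pathology_columns=None):
        self.demographic_columns = demographic_columns
        self.pathology_columns = pathology_columns

    def fit(self, subjects: pd.DataFrame, pathologies: pd.DataFrame,
            features: pd.DataFrame, y=None):
        """``features`` is a subject_id-keyed table of molecular predictors
        (lead dosages, top CpG betas, RNA values); ``y`` defaults to
        ``last_global_cognition``."""
        demo = list(self.demographic_columns or DEMOGRAPHIC_COLUMNS)
        path = list(self.pathology_columns or PATHOLOGY_COLUMNS)
        merged = subjects.merge(pathologies, on="subject_id", validate="1:1")
        merged = merged.merge(features, on="subject_id", validate="1:1")
        merged = merged.set_index("subject_id")
        feat_cols = [c for c in features.columns if c != "subject_id"]
        if y is None:
            yv = merged["last_global_cognition"]
        else:
            yv = pd.Series(np.asarray(y, float)[: len(merged)], index=merged.index)
        cols = demo + path + feat_cols
        X = merged[cols].apply(pd.to_numeric, errors="coerce")
        complete = X.notna().all(axis=1) & yv.notna()
        X, yv = X[complete], yv[complete].to_numpy(float)
        n = len(X)
        p_base, p_full = len(demo) + len(path), len(cols)
        if n <= p_full + 1:
            raise ValueError(f"n={n} too small for {p_full} predictors")
        Xb = X[demo + path].to_numpy(float)
        Xf = X[cols].to_numpy(float)
        r2_base = _ols_r2(Xb, yv, demo + path)
        r2_full = _ols_r2(Xf, yv, cols)
        self.ledger_ = VarianceLedger(
            n=n,
            base_adj_r2=adjusted_r2(r2_base, n, p_base),
            full_adj_r2=adjusted_r2(r2_full, n, p_full),
            base_r2=r2_base,
            full_r2=r2_full,
        )
        return self


def sequential_ledger(
    subjects: pd.DataFrame,
    pathologies: pd.DataFrame,
    features: pd.DataFrame,
    y=None,
    **kwargs,
) -> VarianceLedger:
    """Functional wrapper around :class:`SequentialVariancePartition`."""
    est = SequentialVariancePartition(**kwargs).fit(subjects, pathologies, features, y=y)
    return est.ledger_
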