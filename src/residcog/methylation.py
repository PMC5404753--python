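"""Stage 2: region-level methylation omnibus test.

For a candidate gene, every CpG within 100 kb of its span is regressed on
residual cognition (with batch and bisulfite-conversion covariates), the
per-CpG p-values are combined with Fisher's method, and an empirical
region p-value is obtained by permuting the trait vector and recomputing
the combined statistic.  A lead-SNP-adjusted rerun checks whether genetic
and epigenetic associations are independent.  Missing beta values are
completed beforehand with k-nearest-neighbour imputation (k = 100).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneAnnotation, MethylationSet, OmnibusResult
from .linmod import covariate_basis, partial_regression, partial_regression_many_y, residualize

__all__ = [
    "KNNBetaImputer",
    "knn_impute",
    "region_cpgs",
    "cpg_association",
    "fisher_statistic",
    "omnibus_test",
    "omnibus_adjusted",
    "bh_fdr",
    "MethylationOmnibus",
]

P_FLOOR = 1e-300


class KNNBetaImputer(TransformerMixin, BaseEstimator):
    """k-nearest-neighbour imputation of missing beta values (default k=100).

    Neighbours are subjects, ranked by Euclidean distance over shared
    non-missing CpGs; each missing entry becomes the mean of the CpG's
    value among the k nearest subjects with an observation.  Non-missing
    entries are untouched and the output is complete.
    """

    def __init__(self, k: int = 100):
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).all(axis=1).any():
            raise ValueError("a subject has all CpGs missing; cannot impute")
        k = min(self.k, X.shape[0] - 1) if X.shape[0] > 1 else 1
        self.imputer_ = KNNImputer(n_neighbors=k, weights="uniform")
        self.imputer_.fit(X)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not np.isnan(X).any():
            return X.copy()
        out = self.imputer_.transform(X)
        return np.clip(out, 0.0, 1.0)


def knn_impute(betas: MethylationSet, k: int = 100) -> MethylationSet:
    """Return a complete copy of ``betas`` with NaNs kNN-imputed."""
    imp = KNNBetaImputer(k=k).fit(betas.betas)
    return MethylationSet(
        betas.subject_ids,
        betas.cpg_map,
        imp.transform(betas.betas),
        betas.batch,
        betas.bisulfite_conversion,
    )


def region_cpgs(gene: pd.Series, cpg_map: pd.DataFrame, flank_kb: float = 100.0) -> list[str]:
    """CpG ids on the gene's chromosome with position within
    [start - flank, end + flank] (1-based inclusive)."""
    flank = int(round(flank_kb * 1000))
    lo, hi = int(gene["start"]) - flank, int(gene["end"]) + flank
    sel = (
        (cpg_map["chrom"].astype(str) == str(gene["chrom"]))
        & (cpg_map["pos"] >= lo)
        & (cpg_map["pos"] <= hi)
    )
    return cpg_map.loc[sel, "cpg_id"].tolist()


def cpg_association(beta, trait, tech=None) -> tuple[float, float, float]:
    """OLS of residual cognition on one CpG with technical covariates.

    Returns (beta, se, p) for the CpG term; requires >= 20 complete cases
    and a non-constant CpG.
    """
    beta = np.asarray(beta, dtype=float)
    trait = np.asarray(trait, dtype=float)
    mask = ~(np.isnan(beta) | np.isnan(trait))
    if tech is not None:
        T = np.atleast_2d(np.asarray(tech, dtype=float))
        if T.shape[0] != len(trait):
            T = T.T
        mask &= ~np.isnan(T).any(axis=1)
    n = int(mask.sum())
    if n < 20:
        raise ValueError(f"only {n} complete cases (minimum 20)")
    b, t = beta[mask], trait[mask]
    if b.std(ddof=1) <= 0:
        raise ValueError("constant CpG beta values")
    Tm = T[mask] if tech is not None else None
    est, se, p = partial_regression(b, t, Tm)
    return float(est), float(se), float(p)


def fisher_statistic(p_values) -> float:
    """Fisher's combination statistic T = -2 * sum(ln p_i).

    p-values must lie in (0, 1]; a zero p-value is an error (no silent
    flooring here — callers decide how to handle underflow).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be nonempty")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(-2.0 * np.log(p).sum())


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _floored(p: np.ndarray) -> np.ndarray:
    if (p < P_FLOOR).any():
        warnings.warn("per-CpG p-values below 1e-300 floored before logging")
        return np.maximum(p, P_FLOOR)
    return p


def _omnibus_core(
    betas: np.ndarray,
    cpg_ids: list[str],
    trait: np.ndarray,
    covariates: np.ndarray | None,
    B: int,
    rng: np.random.Generator,
    scheme: str,
) -> tuple[float, float, np.ndarray]:
    """Observed Fisher statistic, empirical p, and per-CpG observed p's.

    One permutation matrix is shared across the region's CpGs so each
    permuted statistic is a valid joint draw.
    """
    n = len(trait)
    _, _, p_obs = partial_regression(betas, trait, covariates)
    p_obs = np.atleast_1d(p_obs)
    T_obs = fisher_statistic(_floored(p_obs))

    perm_idx = np.argsort(rng.random((n, B)), axis=0)  # columns are permutations
    if scheme == "raw":
        Y = trait[perm_idx]
    elif scheme == "freedman_lane":
        Q = covariate_basis(covariates, n)
        resid = residualize(trait, Q)
        fitted = trait - resid
        Y = fitted[:, None] + resid[perm_idx]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    P = partial_regression_many_y(betas, Y, covariates)  # (n_cpgs, B)
    T_perm = -2.0 * np.log(np.maximum(P, P_FLOOR)).sum(axis=0)
    empirical_p = (1.0 + float((T_perm >= T_obs).sum())) / (B + 1.0)
    return T_obs, empirical_p, p_obs


def omnibus_test(
    gene: pd.Series,
    methylation: MethylationSet,
    trait,
    tech=None,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    flank_kb: float = 100.0,
    extra_covariates=None,
    scheme: str = "raw",
    adjusted_for_snp: bool = False,
) -> OmnibusResult:
    """Region-level omnibus test for one gene.

    Per-CpG p-values (linear model with technical covariates) are combined
    with Fisher's method; the empirical p compares the observed statistic
    with ``B`` trait permutations using the add-one convention
    (1 + #{T_perm >= T_obs}) / (B + 1).
    """
    if B <= 0:
        raise ValueError("B must be positive")
    if B < 100:
        warnings.warn(f"B={B} permutations is very small; empirical p is coarse")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = region_cpgs(gene, methylation.cpg_map, flank_kb)
    if not ids:
        raise ValueError(f"no CpGs within {flank_kb} kb of gene {gene['gene_id']}")
    idx = [int(methylation.cpg_map.index[methylation.cpg_map["cpg_id"] == c][0]) for c in ids]
    M = methylation.betas[:, idx]
    if np.isnan(M).any():
        raise ValueError("methylation contains missing values; run knn_impute first")
    trait = np.asarray(trait, dtype=float)
    if tech is None:
        tech = methylation.tech_covariates()
    C = np.atleast_2d(np.asarray(tech, dtype=float))
    if C.shape[0] != len(trait):
        C = C.T
    if extra_covariates is not None:
        E = np.atleast_2d(np.asarray(extra_covariates, dtype=float))
        if E.shape[0] != len(trait):
            E = E.T
        C = np.column_stack([C, E])
    T_obs, emp_p, p_obs = _omnibus_core(M, ids, trait, C, B, rng, scheme)
    per_cpg_fdr = bh_fdr(p_obs)
    top = int(np.argmin(p_obs))
    return OmnibusResult(
        gene_id=str(gene["gene_id"]),
        n_cpgs=len(ids),
        observed_T=T_obs,
        empirical_p=emp_p,
        fdr_q=float("nan"),
        top_cpg=ids[top],
        top_cpg_p=float(p_obs[top]),
        top_cpg_fdr=float(per_cpg_fdr[top]),
        adjusted_for_snp=adjusted_for_snp,
        cpg_ids=ids,
        cpg_p_values=p_obs,
    )


def omnibus_adjusted(
    gene: pd.Series,
    methylation: MethylationSet,
    trait,
    lead_dosage,
    ev_covariates,
    tech=None,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    flank_kb: float = 100.0,
    scheme: str = "raw",
) -> OmnibusResult:
    """Omnibus rerun with the lead SNP dosage and EV1-3 added to every
    per-CpG regression (and present in the permutation model)."""
    lead = np.asarray(lead_dosage, dtype=float)
    ev = np.asarray(ev_covariates, dtype=float).reshape(len(lead), -1)
    extra = np.column_stack([lead, ev])
    return omnibus_test(
        gene, methylation, trait, tech=tech, B=B, seed=seed, flank_kb=flank_kb,
        extra_covariates=extra, scheme=scheme, adjusted_for_snp=True,
    )


class MethylationOmnibus(BaseEstimator):
    """Omnibus methylation testing over a set of candidate regions.

    Parameters
    ----------
    B : number of trait permutations (default 10,000).
    flank_kb : region half-window around the gene span (default 100).
    scheme : "raw" (permute the outcome) or "freedman_lane".
    seed : base seed; each region draws from its own spawned stream so
        regions are independently reproducible.

    Attributes (after fit)
    ----------------------
    results_ : list of OmnibusResult (``fdr_q`` filled across regions)
    table_ : tidy DataFrame of the same results; per-CpG FDR is computed
        across all CpGs tested in all regions of the run.
    """

    def __init__(self, B: int = 10_000, flank_kb: float = 100.0,
                 scheme: str = "raw", seed: int = 0):
        self.B = B
        self.flank_kb = flank_kb
        self.scheme = scheme
        self.seed = seed

    def fit(self, genes: GeneAnnotation | pd.DataFrame, methylation: MethylationSet,
            trait, tech=None, adjust: dict | None = None):
        """Test every gene region; ``adjust`` optionally maps gene_id ->
        (lead_dosage, ev_matrix) for SNP-adjusted reruns."""
        table = genes.table if isinstance(genes, GeneAnnotation) else genes
        ss = np.random.SeedSequence(self.seed)
        streams = [np.random.default_rng(s) for s in ss.spawn(len(table))]
        results = []
        for (_, gene), rng in zip(table.iterrows(), streams):
            res = omnibus_test(
                gene, methylation, trait, tech=tech, B=self.B, seed=rng,
                flank_kb=self.flank_kb, scheme=self.scheme,
            )
            results.append(res)
        qs = bh_fdr([r.empirical_p for r in results]) if results else []
        all_p = np.concatenate([r.cpg_p_values for r in results]) if results else np.array([])
        all_q = bh_fdr(all_p)
        off = 0
        for r, q in zip(results, qs):
            r.fdr_q = float(q)
            span = slice(off, off + r.n_cpgs)
            top_local = int(np.argmin(r.cpg_p_values))
            r.top_cpg_fdr = float(all_q[span][top_local])
            off += r.n_cpgs
        self.results_ = results
        self.adjusted_results_ = {}
        if adjust:
            ss2 = np.random.SeedSequence(self.seed + 1)
            streams2 = {g: np.random.default_rng(s)
                        for g, s in zip(sorted(adjust), ss2.spawn(len(adjust)))}
            for gid, (lead_dosage, ev) in adjust.items():
                gene = table[table["gene_id"] == gid].iloc[0]
                self.adjusted_results_[gid] = omnibus_adjusted(
                    gene, methylation, trait, lead_dosage, ev, tech=tech,
                    B=self.B, seed=streams2[gid], flank_kb=self.flank_kb,
                    scheme=self.scheme,
                )
        self.table_ = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id, "n_cpgs": r.n_cpgs, "observed_T": r.observed_T,
                    "empirical_p": r.empirical_p, "fdr_q": r.fdr_q, "top_cpg": r.top_cpg,
                    "top_cpg_p": r.top_cpg_p, "top_cpg_fdr": r.top_cpg_fdr,
                    "adjusted": r.adjusted_for_snp,
                }
                for r in results
            ]
        )
        return self
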