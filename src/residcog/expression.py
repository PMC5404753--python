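"""Stage 3: transcript-level association with residual cognition,
plus the conditional secondary models.

Expression associations regress residual cognition on a gene's
batch-adjusted FPKM values with four technical covariates (RNA integrity,
log2 total aligned reads, postmortem interval, ribosomal bases).
Conditional models add a TDP-43 stage/severity score or a second SNP to
ask whether a dosage effect survives the conditioning term.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AssocStat
from .linmod import partial_regression

__all__ = ["expression_association", "conditional_association"]


def expression_association(values, trait, tech=None, gene_id: str = "gene") -> AssocStat:
    """OLS of residual cognition on one gene's expression values."""
    values = np.asarray(values, dtype=float)
    trait = np.asarray(trait, dtype=float)
    mask = ~(np.isnan(values) | np.isnan(trait))
    T = None
    if tech is not None:
        T = np.atleast_2d(np.asarray(tech, dtype=float))
        if T.shape[0] != len(trait):
            T = T.T
        mask &= ~np.isnan(T).any(axis=1)
    n = int(mask.sum())
    if n < 20:
        raise ValueError(f"only {n} complete cases (minimum 20)")
    v, t = values[mask], trait[mask]
    if v.std(ddof=1) <= 0:
        raise ValueError("constant expression values")
    beta, se, p = partial_regression(v, t, T[mask] if T is not None else None)
    return AssocStat(gene_id, float(beta), float(se), float(p), n, "meta")


def conditional_association(
    dosage,
    trait,
    conditioning,
    covariates=None,
    predictor_id: str = "snp",
) -> tuple[AssocStat, AssocStat, float]:
    """Marginal and conditioning-adjusted dosage associations.

    ``conditioning`` is entered as a single linear term (ordinal TDP-43
    stage/severity scores, or a second SNP's dosage).  Returns
    (marginal, conditional, attenuation) with
    attenuation = 1 - beta_cond / beta_marg.  Errors when the
    conditioning variable is (near-)collinear with the dosage
    (r² > 0.99) or constant.
    """
    dosage = np.asarray(dosage, dtype=float)
    trait = np.asarray(trait, dtype=float)
    cond = np.asarray(conditioning, dtype=float)
    mask = ~(np.isnan(dosage) | np.isnan(trait) | np.isnan(cond))
    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(trait):
            C = C.T
        mask &= ~np.isnan(C).any(axis=1)
    d, t, c = dosage[mask], trait[mask], cond[mask]
    if c.std(ddof=1) <= 0:
        raise ValueError("conditioning variable is constant")
    if d.std(ddof=1) <= 0:
        raise ValueError("zero variance predictor")
    r2 = np.corrcoef(d, c)[0, 1] ** 2
    if r2 > 0.99:
        raise ValueError(f"conditioning variable collinear with dosage (r2={r2:.3f})")
    n = int(mask.sum())
    Cm = C[mask] if C is not None else None
    b_m, se_m, p_m = partial_regression(d, t, Cm)
    Cc = c[:, None] if Cm is None else np.column_stack([Cm, c])
    b_c, se_c, p_c = partial_regression(d, t, Cc)
    marginal = AssocStat(predictor_id, float(b_m), float(se_m), float(p_m), n, "meta")
    conditional = AssocStat(predictor_id, float(b_c), float(se_c), float(p_c), n, "meta")
    attenuation = float(1.0 - b_c / b_m) if b_m != 0 else float("nan")
    return marginal, conditional, attenuation
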