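"""Stage 1: per-variant association scan, meta-analysis, LD clumping,
gene annotation, expression triage and cis-eQTL checks.

Each variant is tested with an additive linear model (trait ~ dosage +
EV1-3), separately per genotyping platform; platform results are combined
by fixed-effect inverse-variance meta-analysis.  Variants passing the
suggestive threshold (p < 1e-5) are greedily clumped into independent
loci on dosage r² > 0.2 to the lead variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import AssocStat, CandidateGene, Clump, ExpressionTable, GeneAnnotation, GenotypeDosageMatrix
from .linmod import partial_regression

__all__ = [
    "snp_association",
    "meta_analyze",
    "suggestive_filter",
    "ld_r2",
    "ld_clump",
    "annotate_genes",
    "expression_triage",
    "cis_eqtl",
    "AssociationScan",
]

SUGGESTIVE_P = 1e-5
GENOME_WIDE_P = 5e-8
MIN_CASES = 20


def snp_association(dosage, trait, covariates=None, predictor_id: str = "snp",
                    platform: str = "meta") -> AssocStat:
    """Additive per-variant OLS: trait ~ 1 + covariates + dosage.

    ``covariates`` is typically the EV1-3 ancestry matrix.  Requires at
    least 20 complete cases and a polymorphic dosage.
    """
    dosage = np.asarray(dosage, dtype=float)
    trait = np.asarray(trait, dtype=float)
    mask = ~(np.isnan(dosage) | np.isnan(trait))
    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(trait):
            C = C.T
        mask &= ~np.isnan(C).any(axis=1)
    n = int(mask.sum())
    if n < MIN_CASES:
        raise ValueError(f"only {n} complete cases (minimum {MIN_CASES})")
    d, t = dosage[mask], trait[mask]
    if d.std(ddof=1) <= 0:
        raise ValueError("zero variance predictor")
    Cm = C[mask] if C is not None else None
    beta, se, p = partial_regression(d, t, Cm)
    return AssocStat(predictor_id, float(beta), float(se), float(p), n, platform)


def meta_analyze(stats_a: AssocStat | None, stats_b: AssocStat | None) -> AssocStat:
    """Fixed-effect inverse-variance meta-analysis of two platform results.

    beta = sum(b_i/se_i^2)/sum(1/se_i^2), se = 1/sqrt(sum(1/se_i^2)),
    p from the normal reference on beta/se.  A single present platform
    passes through unchanged.
    """
    present = [s for s in (stats_a, stats_b) if s is not None]
    if not present:
        raise ValueError("no platform statistics to meta-analyze")
    if len(present) == 1:
        return present[0]
    a, b = present
    if a.predictor_id != b.predictor_id:
        raise ValueError(f"allele/predictor mismatch: {a.predictor_id} vs {b.predictor_id}")
    w = np.array([1.0 / a.se**2, 1.0 / b.se**2])
    beta = float((a.beta * w[0] + b.beta * w[1]) / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    from scipy import stats as sps

    z = beta / se
    p = float(np.clip(2.0 * sps.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return AssocStat(a.predictor_id, beta, se, p, a.n + b.n, "meta")


def suggestive_filter(stats: list[AssocStat], threshold: float = SUGGESTIVE_P
                      ) -> tuple[list[AssocStat], bool]:
    """Retain associations with p strictly below the suggestive threshold.

    Also reports whether any association reaches genome-wide significance
    (p < 5e-8).
    """
    kept = [s for s in stats if s.p_value < threshold]
    any_genome_wide = any(s.p_value < GENOME_WIDE_P for s in stats)
    return kept, any_genome_wide


def ld_r2(dosage_x, dosage_y) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    x = np.asarray(dosage_x, dtype=float)
    y = np.asarray(dosage_y, dtype=float)
    if x.std(ddof=1) <= 0 or y.std(ddof=1) <= 0:
        raise ValueError("zero variance dosage")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_clump(
    stats: list[AssocStat],
    dosages: GenotypeDosageMatrix,
    r2_threshold: float = 0.2,
) -> list[Clump]:
    """Greedy LD clumping of (suggestive) associations into independent loci.

    Sorted by ascending p (ties broken by chromosome, position), the best
    unassigned variant seeds a clump and absorbs every unassigned variant
    with r² > ``r2_threshold`` to it; repeats until all are assigned.
    """
    if not stats:
        return []
    vm = dosages.variant_map.set_index("variant_id")

    def sort_key(s: AssocStat):
        row = vm.loc[s.predictor_id]
        return (s.p_value, str(row["chrom"]), int(row["pos"]))

    pending = sorted(stats, key=sort_key)
    clumps: list[Clump] = []
    while pending:
        lead = pending.pop(0)
        lead_d = dosages.column(lead.predictor_id)
        members: list[tuple[str, float]] = [(lead.predictor_id, 1.0)]
        remaining = []
        for s in pending:
            r2 = ld_r2(lead_d, dosages.column(s.predictor_id))
            if r2 > r2_threshold:
                members.append((s.predictor_id, r2))
            else:
                remaining.append(s)
        pending = remaining
        rows = vm.loc[[m[0] for m in members]]
        clumps.append(
            Clump(
                lead=lead,
                members=members,
                region_chrom=str(rows["chrom"].iloc[0]),
                region_span=(int(rows["pos"].min()), int(rows["pos"].max())),
            )
        )
    return clumps


def annotate_genes(
    chrom: str,
    pos: int,
    genes: GeneAnnotation,
    window_kb: float = 100.0,
) -> list[CandidateGene]:
    """Genes whose span lies within ``window_kb`` of a lead-SNP position.

    ``signed_distance_kb`` is 0 when the SNP falls inside the gene;
    otherwise positive when the SNP lies 5' of the gene's start on its
    strand and negative when it lies 3' of its end.
    """
    if genes.table.empty:
        return []
    out = []
    for _, g in genes.table.iterrows():
        if str(g["chrom"]) != str(chrom):
            continue
        start, end = int(g["start"]), int(g["end"])
        if start <= pos <= end:
            dist_bp, signed = 0, 0.0
        elif pos < start:
            dist_bp = start - pos
            signed = dist_bp / 1000.0 if g["strand"] == "+" else -dist_bp / 1000.0
        else:
            dist_bp = pos - end
            signed = -dist_bp / 1000.0 if g["strand"] == "+" else dist_bp / 1000.0
        if dist_bp <= window_kb * 1000:
            out.append(CandidateGene(gene_id=str(g["gene_id"]), signed_distance_kb=signed))
    return out


def expression_triage(
    gene: CandidateGene | str, expr: ExpressionTable, min_fraction: float = 0.8
) -> CandidateGene:
    """Flag a candidate gene as brain-expressed when the fraction of
    subjects with non-zero expression strictly exceeds ``min_fraction``."""
    if isinstance(gene, str):
        gene = CandidateGene(gene_id=gene, signed_distance_kb=0.0)
    values = expr.column(gene.gene_id)
    frac = float((values > 0).mean())
    gene.fraction_nonzero = frac
    gene.expressed_flag = frac > min_fraction
    return gene


def cis_eqtl(
    lead_dosage,
    expr: ExpressionTable,
    gene_ids: list[str],
    predictor_id: str = "lead",
) -> list[AssocStat]:
    """cis-eQTL scan: expression ~ dosage + technical covariates, one
    association per candidate gene within the window."""
    tech = expr.tech_matrix()
    out = []
    for gid in gene_ids:
        y = expr.column(gid)
        if np.std(y, ddof=1) <= 0:
            raise ValueError(f"constant expression for {gid}")
        beta, se, p = partial_regression(
            np.asarray(lead_dosage, float), y, tech
        )
        out.append(AssocStat(f"{predictor_id}:{gid}", float(beta), float(se), float(p),
                             len(y), "meta"))
    return out


class AssociationScan(BaseEstimator):
    """Genome-wide per-variant scan with per-platform analysis and meta.

    Parameters
    ----------
    covariate_columns : columns of the subject table used as covariates
        (default EV1-3).
    maf_min, info_min : variant filters applied before testing.
    min_platform_cases : platforms with fewer complete cases are skipped
        and the other platform's result passes through.

    Attributes (after fit)
    ----------------------
    results_ : DataFrame with per-variant meta statistics
        (variant_id, chrom, pos, minor, major, maf, beta, se, p, n, platform)
    per_platform_ : dict of platform label -> DataFrame
    """

    def __init__(self, covariate_columns=("ev1", "ev2", "ev3"),
                 maf_min: float = 0.01, info_min: float = 0.3,
                 min_platform_cases: int = MIN_CASES):
        self.covariate_columns = covariate_columns
        self.maf_min = maf_min
        self.info_min = info_min
        self.min_platform_cases = min_platform_cases

    def fit(self, genotypes: GenotypeDosageMatrix, trait, subjects: pd.DataFrame | None = None,
            covariates=None):
        """Scan every variant; ``trait`` is aligned with genotype rows.

        Covariates come either from ``subjects[covariate_columns]`` or an
        explicit ``covariates`` matrix.
        """
        trait = np.asarray(trait, dtype=float)
        if covariates is None and subjects is not None:
            covariates = subjects[list(self.covariate_columns)].to_numpy(float)
        vm = genotypes.variant_map
        keep = vm["maf"].to_numpy(float) > self.maf_min
        if "info" in vm.columns:
            keep &= vm["info"].to_numpy(float) > self.info_min
        platforms = [p for p in ("A", "B") if (genotypes.platform == p).any()]
        per_platform: dict[str, pd.DataFrame] = {}
        stats_by_platform: dict[str, list] = {}
        for plat in platforms:
            rows_mask = genotypes.platform == plat
            ok = rows_mask & ~np.isnan(trait)
            if covariates is not None:
                ok &= ~np.isnan(covariates).any(axis=1)
            if ok.sum() < self.min_platform_cases:
                stats_by_platform[plat] = [None] * len(vm)
                continue
            D = genotypes.dosages[ok]
            C = covariates[ok] if covariates is not None else None
            t = trait[ok]
            cols = [j for j in range(len(vm)) if keep[j] and D[:, j].std(ddof=1) > 0]
            recs: list = [None] * len(vm)
            if cols:
                beta, se, p = partial_regression(D[:, cols], t, C)
                for idx, j in enumerate(cols):
                    recs[j] = AssocStat(vm["variant_id"].iloc[j], float(beta[idx]),
                                        float(se[idx]), float(p[idx]), int(ok.sum()), plat)
            stats_by_platform[plat] = recs
            per_platform[plat] = _stats_frame(vm, recs)
        meta_stats = []
        for j in range(len(vm)):
            parts = [stats_by_platform[p][j] for p in platforms if stats_by_platform.get(p)]
            parts = [s for s in parts if s is not None]
            if not parts:
                meta_stats.append(None)
            elif len(parts) == 1:
                s = parts[0]
                meta_stats.append(AssocStat(s.predictor_id, s.beta, s.se, s.p_value, s.n, "meta"))
            else:
                meta_stats.append(meta_analyze(parts[0], parts[1]))
        self.per_platform_ = per_platform
        self.meta_stats_ = [s for s in meta_stats if s is not None]
        self.results_ = _stats_frame(vm, meta_stats)
        return self


def _stats_frame(vm: pd.DataFrame, stats: list) -> pd.DataFrame:
    rows = []
    for j, s in enumerate(stats):
        if s is None:
            continue
        rows.append(
            {
                "variant_id": vm["variant_id"].iloc[j],
                "chrom": vm["chrom"].iloc[j],
                "pos": int(vm["pos"].iloc[j]),
                "minor": vm["minor"].iloc[j],
                "major": vm["major"].iloc[j],
                "maf": float(vm["maf"].iloc[j]),
                "beta": s.beta,
                "se": s.se,
                "p": s.p_value,
                "n": s.n,
                "platform": s.platform,
            }
        )
    return pd.DataFrame(rows)
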