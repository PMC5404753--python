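"""Core data containers shared across the pipeline stages.

The containers are light dataclasses around pandas/numpy objects: the
analysis code operates on plain arrays and DataFrames, and these classes
mainly enforce the domain invariants (dosage range, beta-value range,
coordinate conventions) at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDosageMatrix",
    "CognitionBattery",
    "MethylationSet",
    "ExpressionTable",
    "GeneAnnotation",
    "AssocStat",
    "Clump",
    "CandidateGene",
    "OmnibusResult",
    "VarianceLedger",
]

#: Columns of the ten-pathology profile used to derive residual cognition.
PATHOLOGY_COLUMNS = [
    "tangles",
    "neuritic_plaques",
    "diffuse_plaques",
    "caa",
    "atherosclerosis",
    "arteriolosclerosis",
    "macroinfarcts",
    "microinfarcts",
    "lewy_bodies",
    "hippocampal_sclerosis",
]

#: Demographic covariates of the residual-cognition model.
DEMOGRAPHIC_COLUMNS = ["age_at_death", "sex", "education", "cohort"]


@dataclass
class GenotypeDosageMatrix:
    """Subjects x variants imputed dosage matrix with a variant map.

    Dosages are expected minor-allele counts in [0, 2]; ``platform`` labels
    each subject's genotyping platform ("A" or "B").  ``variant_map`` has
    columns ``variant_id, chrom, pos, major, minor, maf`` (1-based positions).
    """

    subject_ids: list[str]
    variant_map: pd.DataFrame
    dosages: np.ndarray
    platform: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.platform = np.asarray(self.platform, dtype=object)
        n, m = self.dosages.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match dosage rows")
        if len(self.variant_map) != m:
            raise ValueError("variant_map length does not match dosage columns")
        if self.dosages.size:
            if np.isnan(self.dosages).any():
                raise ValueError("dosage matrix contains missing entries")
            if self.dosages.min() < 0 or self.dosages.max() > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def empirical_maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency implied by the dosages."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variant_map.index[self.variant_map["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant {variant_id!r}")
        return self.dosages[:, int(idx[0])]


@dataclass
class CognitionBattery:
    """Seventeen-test cognitive battery with per-visit global trajectories.

    ``test_scores`` holds the raw final-visit scores; ``baseline_means`` and
    ``baseline_sds`` are the baseline normalisation constants used for
    z-scoring.  ``visit_times`` are years before death (0 = last visit) and
    ``global_trajectory`` the matching per-visit global z-scores.
    """

    subject_ids: list[str]
    test_scores: np.ndarray
    baseline_means: np.ndarray
    baseline_sds: np.ndarray
    global_cognition: np.ndarray
    baseline_global: np.ndarray
    visit_times: list[np.ndarray]
    global_trajectory: list[np.ndarray]

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.baseline_sds) <= 0):
            raise ValueError("baseline SDs must be positive")


@dataclass
class MethylationSet:
    """Subjects x CpGs beta-value matrix with technical covariates.

    Beta values are methylated fractions in [0, 1]; missing entries are NaN.
    ``cpg_map`` has columns ``cpg_id, chrom, pos``.
    """

    subject_ids: list[str]
    cpg_map: pd.DataFrame
    betas: np.ndarray
    batch: np.ndarray
    bisulfite_conversion: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        ok = self.betas[~np.isnan(self.betas)]
        if ok.size and (ok.min() < 0 or ok.max() > 1):
            raise ValueError("non-missing beta values must lie in [0, 1]")
        if self.betas.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length does not match beta rows")
        if self.betas.shape[1] != len(self.cpg_map):
            raise ValueError("cpg_map length does not match beta columns")

    def tech_covariates(self) -> np.ndarray:
        """Technical design: batch indicators + mean bisulfite conversion."""
        batches = pd.get_dummies(pd.Series(self.batch), drop_first=True)
        return np.column_stack(
            [batches.to_numpy(dtype=float), np.asarray(self.bisulfite_conversion, float)]
        )

    def column(self, cpg_id: str) -> np.ndarray:
        idx = self.cpg_map.index[self.cpg_map["cpg_id"] == cpg_id]
        if len(idx) == 0:
            raise KeyError(f"unknown CpG {cpg_id!r}")
        return self.betas[:, int(idx[0])]


@dataclass
class ExpressionTable:
    """Subjects x genes batch-adjusted FPKM-like expression values.

    ``tech_covariates`` is a DataFrame with columns
    ``rin, log2_aligned_reads, pmi_hours, ribosomal_bases``.
    """

    subject_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    tech_covariates: pd.DataFrame

    TECH_COLUMNS = ("rin", "log2_aligned_reads", "pmi_hours", "ribosomal_bases")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if not np.isfinite(self.tech_covariates.to_numpy(float)).all():
            raise ValueError("technical covariates must be finite")

    def column(self, gene_id: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} absent from expression table") from None
        return self.values[:, j]

    def tech_matrix(self) -> np.ndarray:
        return self.tech_covariates.loc[:, list(self.TECH_COLUMNS)].to_numpy(float)


@dataclass
class GeneAnnotation:
    """Gene coordinate table (1-based inclusive start/end, strand +/-)."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        if t["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")
        if (t["start"] > t["end"]).any():
            raise ValueError("gene start must be <= end")
        if not t["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")

    def row(self, gene_id: str) -> pd.Series:
        hit = self.table[self.table["gene_id"] == gene_id]
        if hit.empty:
            raise KeyError(f"unknown gene {gene_id!r}")
        return hit.iloc[0]


@dataclass
class AssocStat:
    """One predictor-trait association: effect, SE, p, sample size."""

    predictor_id: str
    beta: float
    se: float
    p_value: float
    n: int
    platform: str = "meta"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


@dataclass
class Clump:
    """An independent locus: lead association plus absorbed members."""

    lead: AssocStat
    members: list[tuple[str, float]]  # (variant_id, r2 to lead)
    region_chrom: str
    region_span: tuple[int, int]


@dataclass
class CandidateGene:
    """Gene near a lead SNP, annotated with distance and expression triage."""

    gene_id: str
    signed_distance_kb: float
    expressed_flag: bool = False
    fraction_nonzero: float = 0.0


@dataclass
class OmnibusResult:
    """Region-level methylation omnibus test result."""

    gene_id: str
    n_cpgs: int
    observed_T: float
    empirical_p: float
    fdr_q: float
    top_cpg: str
    top_cpg_p: float
    top_cpg_fdr: float
    adjusted_for_snp: bool
    cpg_ids: list[str] = field(default_factory=list)
    cpg_p_values: np.ndarray | None = None


@dataclass
class VarianceLedger:
    """Sequential adjusted-R² bookkeeping for last global cognition."""

    n: int
    base_adj_r2: float
    full_adj_r2: float
    base_r2: float
    full_r2: float

    @property
    def increment(self) -> float:
        return self.full_adj_r2 - self.base_adj_r2

    @property
    def unexplained(self) -> float:
        return 1.0 - self.full_adj_r2

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "base_adj_r2": self.base_adj_r2,
            "full_adj_r2": self.full_adj_r2,
            "increment": self.increment,
            "unexplained": self.unexplained,
        }
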