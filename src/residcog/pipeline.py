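"""Orchestrates the three-stage convergence analysis.

Stage 1 scans the genome for residual-cognition associations, clumps the
suggestive variants into independent loci, and annotates genes within
100 kb of each lead SNP, keeping those expressed in >80% of subjects.
Stage 2 runs the region-level methylation omnibus test for each retained
gene (with a SNP-adjusted rerun for significant regions).  Stage 3 tests
each gene's RNA level.  A gene is called "convergent" when it has a
suggestive SNP, omnibus FDR below threshold, and expression p below
threshold; "partial" with one of the two molecular confirmations;
"genetic-only" with neither.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datatypes import GeneAnnotation
from .genetics import AssociationScan, annotate_genes, cis_eqtl, expression_triage, ld_clump, suggestive_filter
from .datatypes import AssocStat
from .expression import expression_association
from .methylation import MethylationOmnibus, knn_impute
from .phenotype import compute_residual_cognition
from .simulate import CohortBundle
from .variance import sequential_ledger

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline", "assemble_report"]

log = logging.getLogger("residcog.pipeline")


@dataclass
class PipelineParams:
    """Thresholds of the multistep procedure (defaults as predefined)."""

    p_suggestive: float = 1e-5
    r2_clump: float = 0.2
    window_kb: float = 100.0
    expr_fraction: float = 0.8
    B: int = 10_000
    fdr: float = 0.05
    expr_p: float = 0.05
    knn_k: int = 100
    scheme: str = "raw"

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})


@dataclass
class PipelineResult:
    residual_model: object
    subjects: pd.DataFrame
    scan: pd.DataFrame
    clumps: list
    candidates: pd.DataFrame
    omnibus: pd.DataFrame
    expression: pd.DataFrame
    eqtl: pd.DataFrame
    report: pd.DataFrame
    ledger: object | None
    any_genome_wide: bool = False
    intermediates: dict = field(default_factory=dict)


def _check_alignment(bundle: CohortBundle) -> None:
    base = list(bundle.subjects["subject_id"])
    for name, ids in (
        ("genotypes", bundle.genotypes.subject_ids),
        ("methylation", bundle.methylation.subject_ids),
        ("expression", bundle.expression.subject_ids),
        ("pathologies", list(bundle.pathologies["subject_id"])),
    ):
        extra = sorted(set(ids) - set(base))
        if extra:
            raise ValueError(f"subject ids in {name} absent from subject table: {extra[:10]}")
        if list(ids) != base:
            raise ValueError(f"subject order of {name} does not match the subject table")


def assemble_report(
    candidates: pd.DataFrame,
    omnibus: pd.DataFrame,
    expression: pd.DataFrame,
    eqtl: pd.DataFrame,
    params: PipelineParams,
) -> pd.DataFrame:
    """Pure verdict assembly from the three stage tables.

    Reproducible from the written intermediate TSVs: the verdict of each
    candidate gene is a function only of these inputs.
    """
    rows = []
    omni = omnibus.set_index("gene_id") if len(omnibus) else pd.DataFrame()
    expr = expression.set_index("gene_id") if len(expression) else pd.DataFrame()
    eq = eqtl.set_index("gene_id") if len(eqtl) else pd.DataFrame()
    for _, cand in candidates.iterrows():
        gid = cand["gene_id"]
        rec = dict(cand)
        has_omni = gid in getattr(omni, "index", [])
        has_expr = gid in getattr(expr, "index", [])
        rec["omnibus_p"] = float(omni.loc[gid, "empirical_p"]) if has_omni else np.nan
        rec["omnibus_fdr"] = float(omni.loc[gid, "fdr_q"]) if has_omni else np.nan
        rec["top_cpg"] = omni.loc[gid, "top_cpg"] if has_omni else ""
        rec["expr_beta"] = float(expr.loc[gid, "beta"]) if has_expr else np.nan
        rec["expr_p"] = float(expr.loc[gid, "p"]) if has_expr else np.nan
        rec["eqtl_beta"] = float(eq.loc[gid, "beta"]) if gid in getattr(eq, "index", []) else np.nan
        rec["eqtl_p"] = float(eq.loc[gid, "p"]) if gid in getattr(eq, "index", []) else np.nan
        meth_ok = has_omni and rec["omnibus_fdr"] < params.fdr
        expr_ok = has_expr and rec["expr_p"] < params.expr_p
        if meth_ok and expr_ok:
            rec["verdict"] = "convergent"
        elif meth_ok or expr_ok:
            rec["verdict"] = "partial"
        else:
            rec["verdict"] = "genetic-only"
        rows.append(rec)
    cols = [
        "gene_id", "lead_variant", "lead_beta", "lead_se", "lead_p", "signed_distance_kb",
        "fraction_nonzero", "expressed", "omnibus_p", "omnibus_fdr", "top_cpg",
        "expr_beta", "expr_p", "eqtl_beta", "eqtl_p", "verdict",
    ]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def run_pipeline(
    bundle: CohortBundle,
    params: PipelineParams | None = None,
    seed: int = 0,
    outdir: str | None = None,
) -> PipelineResult:
    """Run the full multistep analysis on a cohort bundle.

    All randomness (the omnibus permutations) flows from ``seed`` through
    spawned per-stage streams, so each stage is independently
    reproducible.
    """
    params = params or PipelineParams()
    _check_alignment(bundle)
    root = np.random.SeedSequence(seed)
    seed_omnibus, _seed_spare = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2)]

    # stage 0: trait
    subjects, residual_model = compute_residual_cognition(bundle.subjects, bundle.pathologies)
    trait = subjects["residual_cognition"].to_numpy(float)
    log.info("residual model: n=%d adj_r2=%.3f", residual_model.n_, residual_model.adjusted_r_squared_)

    # stage 1: genetic scan
    scan = AssociationScan().fit(bundle.genotypes, trait, subjects=subjects)
    stats = scan.meta_stats_
    suggestive, any_gw = suggestive_filter(stats, params.p_suggestive)
    clumps = ld_clump(suggestive, bundle.genotypes, params.r2_clump)
    log.info("scan: %d variants, %d suggestive, %d clumps", len(stats), len(suggestive), len(clumps))

    vm = bundle.genotypes.variant_map.set_index("variant_id")
    ev = subjects[["ev1", "ev2", "ev3"]].to_numpy(float)
    cand_rows = []
    eqtl_rows = []
    for clump in clumps:
        lead = clump.lead
        pos = int(vm.loc[lead.predictor_id, "pos"])
        chrom = str(vm.loc[lead.predictor_id, "chrom"])
        genes_near = annotate_genes(chrom, pos, bundle.genes, params.window_kb)
        lead_dosage = bundle.genotypes.column(lead.predictor_id)
        in_expr = [g for g in genes_near if g.gene_id in bundle.expression.gene_ids]
        if in_expr:
            for st in cis_eqtl(lead_dosage, bundle.expression,
                               [g.gene_id for g in in_expr], lead.predictor_id):
                eqtl_rows.append(
                    {"gene_id": st.predictor_id.split(":", 1)[1], "lead_variant": lead.predictor_id,
                     "beta": st.beta, "se": st.se, "p": st.p_value, "n": st.n}
                )
        for g in genes_near:
            if g.gene_id in bundle.expression.gene_ids:
                g = expression_triage(g, bundle.expression, params.expr_fraction)
            cand_rows.append(
                {
                    "gene_id": g.gene_id, "lead_variant": lead.predictor_id,
                    "lead_beta": lead.beta, "lead_se": lead.se, "lead_p": lead.p_value,
                    "signed_distance_kb": g.signed_distance_kb,
                    "fraction_nonzero": g.fraction_nonzero, "expressed": g.expressed_flag,
                }
            )
    candidates = pd.DataFrame(
        cand_rows,
        columns=["gene_id", "lead_variant", "lead_beta", "lead_se", "lead_p",
                 "signed_distance_kb", "fraction_nonzero", "expressed"],
    )
    eqtl = pd.DataFrame(eqtl_rows, columns=["gene_id", "lead_variant", "beta", "se", "p", "n"])

    retained = candidates[candidates["expressed"].astype(bool)].drop_duplicates("gene_id")
    log.info("candidates: %d genes near leads, %d expressed", candidates["gene_id"].nunique(), len(retained))

    # stage 2: methylation omnibus on retained genes
    omnibus_df = pd.DataFrame(
        columns=["gene_id", "n_cpgs", "observed_T", "empirical_p", "fdr_q",
                 "top_cpg", "top_cpg_p", "top_cpg_fdr", "adjusted"]
    )
    omni_model = None
    if len(retained):
        meth = bundle.methylation
        if np.isnan(meth.betas).any():
            meth = knn_impute(meth, k=params.knn_k)
        gene_table = bundle.genes.table[bundle.genes.table["gene_id"].isin(retained["gene_id"])]
        gene_table = gene_table.reset_index(drop=True)
        omni_model = MethylationOmnibus(
            B=params.B, flank_kb=params.window_kb, scheme=params.scheme, seed=seed_omnibus
        ).fit(GeneAnnotation(gene_table), meth, trait)
        omnibus_df = omni_model.table_
        # SNP-adjusted rerun for significant regions
        sig = omnibus_df[omnibus_df["fdr_q"] < params.fdr]["gene_id"]
        adjust = {}
        for gid in sig:
            lead_id = retained[retained["gene_id"] == gid]["lead_variant"].iloc[0]
            adjust[gid] = (bundle.genotypes.column(lead_id), ev)
        if adjust:
            from .methylation import omnibus_adjusted

            ss_adj = np.random.SeedSequence(seed_omnibus + 1)
            streams = {g: np.random.default_rng(s)
                       for g, s in zip(sorted(adjust), ss_adj.spawn(len(adjust)))}
            adj_rows = []
            for gid, (lead_dosage, ev_mat) in adjust.items():
                gene = gene_table[gene_table["gene_id"] == gid].iloc[0]
                r = omnibus_adjusted(
                    gene, meth, trait, lead_dosage, ev_mat, B=params.B,
                    seed=streams[gid], flank_kb=params.window_kb, scheme=params.scheme,
                )
                adj_rows.append(
                    {"gene_id": gid, "n_cpgs": r.n_cpgs, "observed_T": r.observed_T,
                     "empirical_p": r.empirical_p, "fdr_q": np.nan, "top_cpg": r.top_cpg,
                     "top_cpg_p": r.top_cpg_p, "top_cpg_fdr": r.top_cpg_fdr, "adjusted": True}
                )
            omnibus_df = pd.concat([omnibus_df, pd.DataFrame(adj_rows)], ignore_index=True)

    # stage 3: expression association
    expr_rows = []
    tech = bundle.expression.tech_matrix()
    for gid in retained["gene_id"]:
        st = expression_association(bundle.expression.column(gid), trait, tech, gene_id=gid)
        expr_rows.append({"gene_id": gid, "beta": st.beta, "se": st.se, "p": st.p_value, "n": st.n})
    expression_df = pd.DataFrame(expr_rows, columns=["gene_id", "beta", "se", "p", "n"])

    unadjusted = omnibus_df[~omnibus_df["adjusted"].astype(bool)] if len(omnibus_df) else omnibus_df
    report = assemble_report(candidates, unadjusted, expression_df, eqtl, params)

    # variance ledger over the convergence candidates
    ledger = None
    if len(retained):
        feats = {"subject_id": bundle.subjects["subject_id"]}
        omni_idx = unadjusted.set_index("gene_id") if len(unadjusted) else pd.DataFrame()
        for _, row in retained.iterrows():
            gid = row["gene_id"]
            feats[f"snp_{row['lead_variant']}"] = bundle.genotypes.column(row["lead_variant"])
            if gid in getattr(omni_idx, "index", []):
                top = omni_idx.loc[gid, "top_cpg"]
                meth_src = bundle.methylation
                col = meth_src.column(top)
                if np.isnan(col).any():
                    col = knn_impute(meth_src, k=params.knn_k).column(top)
                feats[f"cpg_{top}"] = col
            feats[f"rna_{gid}"] = bundle.expression.column(gid)
        ledger = sequential_ledger(bundle.subjects, bundle.pathologies, pd.DataFrame(feats))

    result = PipelineResult(
        residual_model=residual_model,
        subjects=subjects,
        scan=scan.results_,
        clumps=clumps,
        candidates=candidates,
        omnibus=omnibus_df,
        expression=expression_df,
        eqtl=eqtl,
        report=report,
        ledger=ledger,
        any_genome_wide=any_gw,
    )
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    result.subjects.to_csv(p("subjects_with_residual.tsv"), sep="\t", index=False)
    result.scan.to_csv(p("association_scan.tsv"), sep="\t", index=False)
    clump_rows = [
        {"lead_variant": c.lead.predictor_id, "lead_p": c.lead.p_value,
         "chrom": c.region_chrom, "span_start": c.region_span[0], "span_end": c.region_span[1],
         "n_members": len(c.members),
         "members": ",".join(m for m, _ in c.members)}
        for c in result.clumps
    ]
    pd.DataFrame(clump_rows, columns=["lead_variant", "lead_p", "chrom", "span_start",
                                      "span_end", "n_members", "members"]).to_csv(
        p("clumps.tsv"), sep="\t", index=False)
    result.candidates.to_csv(p("candidate_genes.tsv"), sep="\t", index=False)
    result.omnibus.to_csv(p("omnibus.tsv"), sep="\t", index=False)
    result.expression.to_csv(p("expression_assoc.tsv"), sep="\t", index=False)
    result.eqtl.to_csv(p("cis_eqtl.tsv"), sep="\t", index=False)
    result.report.to_csv(p("convergence_report.tsv"), sep="\t", index=False)
    if result.ledger is not None:
        with open(p("variance_ledger.yaml"), "w") as fh:
            yaml.safe_dump(result.ledger.as_dict(), fh)
        pd.DataFrame([result.ledger.as_dict()]).to_csv(p("variance_ledger.tsv"), sep="\t", index=False)
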