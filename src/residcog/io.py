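"""Readers and writers for the pipeline's on-disk formats.

Matrices are TSV with subjects as rows and a leading ``subject_id``
column; gene annotation is a BED-like TSV with 1-based inclusive
coordinates; dosages can also be exchanged as VCF 4.2 with a per-sample
``DS`` FORMAT field; the truth ledger is YAML.
"""

from __future__ import annotations

import os
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .datatypes import ExpressionTable, GeneAnnotation, GenotypeDosageMatrix, MethylationSet
from .simulate import CohortBundle

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_gene_annotation",
    "read_gene_annotation",
    "write_dosage_vcf",
    "read_dosage_vcf",
    "write_truth_yaml",
    "read_truth_yaml",
    "write_bundle",
]


def write_matrix_tsv(path, subject_ids, column_ids, values) -> None:
    """Subjects-as-rows TSV with a leading ``subject_id`` column."""
    df = pd.DataFrame(np.asarray(values), columns=list(column_ids))
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    subject_ids = df["subject_id"].astype(str).tolist()
    cols = [c for c in df.columns if c != "subject_id"]
    return subject_ids, cols, df[cols].to_numpy(float)


def write_gene_annotation(path, genes: GeneAnnotation) -> None:
    genes.table[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
        path, sep="\t", index=False
    )


def read_gene_annotation(path) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_dosage_vcf(path, genotypes: GenotypeDosageMatrix) -> None:
    """Minimal VCF 4.2 with FORMAT ``DS`` (expected minor-allele dosage)."""
    vm = genotypes.variant_map
    order = np.lexsort((vm["pos"].to_numpy(), vm["chrom"].astype(str).to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        for chrom in pd.unique(vm["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids)
            + "\n"
        )
        for j in order:
            row = vm.iloc[j]
            ds = "\t".join(f"{v:.3f}" for v in genotypes.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['variant_id']}\t"
                f"{row['major']}\t{row['minor']}\t.\tPASS\t.\tDS\t{ds}\n"
            )


def read_dosage_vcf(path, platform=None) -> GenotypeDosageMatrix:
    """Read a DS-format VCF back into a dosage matrix (requires cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        rows.append(
            {
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "major": var.REF,
                "minor": var.ALT[0] if var.ALT else ".",
            }
        )
        cols.append(np.asarray(var.format("DS"), dtype=float).ravel())
    vm = pd.DataFrame(rows)
    dosages = np.column_stack(cols) if cols else np.empty((len(subject_ids), 0))
    freq = dosages.mean(axis=0) / 2 if len(cols) else np.array([])
    vm["maf"] = np.minimum(freq, 1 - freq)
    if platform is None:
        platform = np.array(["A"] * len(subject_ids), dtype=object)
    return GenotypeDosageMatrix(subject_ids, vm, dosages, platform)


def write_truth_yaml(path, truth: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


def read_truth_yaml(path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_bundle(bundle: CohortBundle, outdir) -> None:
    """Write every table of a simulated cohort under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    bundle.subjects.to_csv(p("subjects.tsv"), sep="\t", index=False)
    bundle.pathologies.to_csv(p("pathologies.tsv"), sep="\t", index=False)
    write_gene_annotation(p("genes.tsv"), bundle.genes)
    write_dosage_vcf(p("dosages.vcf"), bundle.genotypes)
    write_matrix_tsv(
        p("dosages.tsv"),
        bundle.genotypes.subject_ids,
        bundle.genotypes.variant_map["variant_id"],
        bundle.genotypes.dosages,
    )
    pd.DataFrame(
        {"subject_id": bundle.genotypes.subject_ids, "platform": bundle.genotypes.platform}
    ).to_csv(p("platforms.tsv"), sep="\t", index=False)
    write_matrix_tsv(
        p("methylation.tsv"),
        bundle.methylation.subject_ids,
        bundle.methylation.cpg_map["cpg_id"],
        bundle.methylation.betas,
    )
    bundle.methylation.cpg_map.to_csv(p("cpg_map.tsv"), sep="\t", index=False)
    meth_cov = pd.DataFrame(
        {
            "subject_id": bundle.methylation.subject_ids,
            "batch": bundle.methylation.batch,
            "bisulfite_conversion": bundle.methylation.bisulfite_conversion,
        }
    )
    meth_cov.to_csv(p("methylation_covariates.tsv"), sep="\t", index=False)
    write_matrix_tsv(
        p("expression.tsv"),
        bundle.expression.subject_ids,
        bundle.expression.gene_ids,
        bundle.expression.values,
    )
    tech = bundle.expression.tech_covariates.copy()
    tech.insert(0, "subject_id", bundle.expression.subject_ids)
    tech.to_csv(p("expression_covariates.tsv"), sep="\t", index=False)
    write_truth_yaml(p("truth.yaml"), bundle.truth)
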