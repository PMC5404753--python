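# residcog

Multistep convergence analysis for **residual cognition** — the part of
late-life cognitive performance that neuropathology and demographics do
not explain — together with a seeded synthetic multi-omic cohort
generator that makes every stage verifiable against planted ground
truth.

## The scientific problem

In community-based autopsy cohorts of older adults, quantitative indices
of common brain pathologies (neurofibrillary tangles, neuritic and
diffuse plaques, Lewy bodies, infarcts, vascular pathologies, cerebral
amyloid angiopathy, hippocampal sclerosis) together with demographics
explain well under half of the variance in cognition proximate to death.
Some people function better than their pathological burden predicts,
others worse. This package implements, as a tested reusable pipeline,
a multistep strategy for finding genes whose genetic, epigenetic and
transcriptomic variation *converge* on that residual:

1. **Trait.** Residual cognition is the residual of a linear model
   `global_cognition ~ age_at_death + sex + education + cohort + 10 pathologies`,
   where global cognition is the mean of 17 z-scored neuropsychological
   tests.
2. **Step 1 — genetic scan.** Every variant is tested additively
   (`residual ~ dosage + EV1–3`), separately per genotyping platform,
   combined by fixed-effect inverse-variance meta-analysis. Variants
   with p < 1e-5 (suggestive; genome-wide significance 5e-8 is also
   flagged) are greedily clumped into independent loci at dosage
   r² > 0.2; genes within 100 kb of each lead SNP that show non-zero
   brain expression in > 80% of subjects become candidates, and each
   lead SNP is checked for a cis-eQTL effect on them.
3. **Step 2 — methylation omnibus.** For each candidate gene, all CpGs
   within 100 kb of its span are regressed on the trait (with batch and
   bisulfite-conversion covariates); the per-CpG p-values are combined
   with Fisher's method, T = −2 Σ ln pᵢ, and an empirical region-level
   p-value comes from permuting the trait (default B = 10,000), with
   Benjamini–Hochberg FDR across regions and a lead-SNP-adjusted rerun
   for significant regions. Missing beta values are completed by
   k-nearest-neighbour imputation (k = 100).
4. **Step 3 — expression.** Each candidate gene's adjusted-FPKM values
   are regressed on the trait with four technical covariates (RIN,
   log₂ aligned reads, postmortem interval, ribosomal bases).
5. **Verdict & variance ledger.** A gene with a suggestive SNP, omnibus
   FDR < 0.05 and expression p < 0.05 is *convergent*. A sequential
   adjusted-R² ledger quantifies how much variance in last global
   cognition the molecular features add over demographics + pathology:
   adj R² = 1 − (1 − R²)(n − 1)/(n − p − 1).

Because real cohorts of this kind are controlled-access, the
`simulate_cohort` generator emulates the data: ~979 subjects on two
genotyping platforms, block-LD dosages in [0, 2] with MAF ≥ 0.01, ten
pathology indices with realistic codings, a 17-test battery with
pathology-driven decline, CpG betas in [0, 1] with regional correlation
and technical covariates, FPKM-like expression, and planted SNP/CpG/RNA
effects recorded in a truth ledger.

## Worked example

```python
import residcog as rc

cfg = rc.SimConfig.study_defaults(seed=7)      # 979 subjects, planted loci
bundle = rc.simulate_cohort(cfg)
result = rc.run_pipeline(bundle, rc.PipelineParams(B=10_000), seed=7)

print(result.report[["gene_id", "lead_variant", "lead_beta", "lead_p",
                     "omnibus_fdr", "expr_p", "verdict"]].to_string(index=False))
print(result.ledger.as_dict())
```

prints

```
gene_id lead_variant  lead_beta       lead_p  omnibus_fdr   expr_p      verdict
     G1        v0035  -0.550442 9.719193e-09     0.005599 0.001576   convergent
     G3        v0055   0.261943 4.203491e-07     0.225677 0.765543 genetic-only

{'n': 979, 'base_adj_r2': 0.438, 'full_adj_r2': 0.484, 'increment': 0.046, 'unexplained': 0.516}
```

Reading: two planted loci cleared the suggestive threshold this seed.
Gene `G1` (a deleterious low-MAF locus planted with SNP −0.42/allele,
plus methylation and RNA effects) shows all three lines of evidence and
is called convergent; `G3` (a common allele planted with a SNP effect
only, plus a cis-eQTL on its own expression) is genetic-only, as it
should be. Demographics + pathology explain 43.8% of the variance in
last global cognition; the molecular features add 4.6%; 51.6% remains
unexplained. Run-to-run variation in which loci clear p < 1e-5 is
expected — at these effect sizes and n = 979 each locus has roughly
coin-flip power, which is precisely the regime the multistep design is
built for.

The same analysis is scriptable from a shell:

```bash
residcog simulate --out cohort --seed 7          # study-scale defaults
residcog run --cohort cohort --out results --seed 7
residcog scan --cohort cohort --out assoc.tsv    # or stage by stage
residcog clump --cohort cohort --assoc assoc.tsv --out clumps.tsv
residcog omnibus --cohort cohort --genes G1 -B 10000 --seed 7 --out omni.tsv
```

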