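# Methods

This note documents the statistical procedures the package implements,
the synthetic cohort that exercises them, and the numerical conventions
adopted where the procedure definition leaves room.

## The trait: residual cognition

Global cognition is the mean of 17 test z-scores, each standardized by
its baseline mean and SD; a subject's score is computed when at least
half the battery is observed (configurable). The trait of every
downstream analysis is the residual of

    last_global_cognition ~ age_at_death + sex + education + cohort
                            + tangles + neuritic_plaques + diffuse_plaques
                            + caa + atherosclerosis + arteriolosclerosis
                            + macroinfarcts + microinfarcts + lewy_bodies
                            + hippocampal_sclerosis

fit by OLS on complete cases (≥ 20 required; a rank-deficient design is
an error naming the collinear columns). TDP-43 measures are deliberately
excluded from this model and enter only the conditional secondary
analyses. Residuals are orthogonal to every covariate by construction
(asserted to 1e-6 in tests).

Pathology composites follow the field's construction: regional counts
are scaled and the composite is the square root of the regional mean.
The regional "scaling" is division by the region's baseline SD
*without centering* — centering would produce negatives incompatible
with the square root. The CAA score is the plain mean of four
neocortical grades in [0, 4]. Cohort-combined baselines are used for
scaling (configurable; cohort-specific baselines are a defensible
alternative).

Per-subject cognitive decline slopes are ordinary least-squares slopes
of global cognition on time, requiring ≥ 3 visits (fewer yields a
flagged missing value). This replaces a mixed-model fit: the mixed
model is peripheral to the headline procedure, and the per-subject OLS
slope preserves the contract of "a decline rate per subject" with far
less machinery. This is a documented simplification.

## Stage 1: genetic scan

Each variant is tested with `trait ~ 1 + EV1 + EV2 + EV3 + dosage`
(additive coding, dosage in [0, 2]); p-values use the t reference with
n − k − 1 df. Variants are filtered at MAF > 0.01 and INFO > 0.3 (the
simulator emits INFO = 1). Platforms are analysed separately and
combined by fixed-effect inverse-variance meta-analysis
(β = Σβᵢ/seᵢ² / Σ1/seᵢ², se = (Σ1/seᵢ²)^(−1/2), normal p) — the
standard reading of a summary-statistic meta-analysis; a platform with
too few complete cases passes the other platform through unchanged.

Clumping is greedy and lead-only, matching the common GWAS tool
default: sort suggestive variants by ascending p (ties broken by
chromosome then position, for determinism); the best unassigned variant
seeds a clump and absorbs all unassigned variants with dosage r² > 0.2
to *it* (not pairwise); repeat. LD is the squared Pearson correlation
of dosages, not a phased-haplotype estimator — dosages are what the
pipeline holds, and the divergence matters only near the r² threshold.

Gene annotation uses 1-based inclusive coordinates and retains genes
whose span lies within ≤ 100,000 bp of the lead SNP. The signed
distance is 0 inside the gene, positive when the SNP lies 5′ of the
gene's start on its strand, negative 3′ of its end. Expression triage
keeps genes with non-zero expression in strictly more than 80% of
subjects. cis-eQTL checks regress expression on dosage with the four
technical covariates.

## Stage 2: methylation omnibus

Missing beta values are first completed by k-nearest-neighbour
imputation, k = 100 (capped at n − 1): neighbours are subjects under
nan-aware Euclidean distance over shared CpGs, and a missing entry is
the mean of the CpG among the k nearest subjects with data
(scikit-learn's `KNNImputer` implements exactly this contract and backs
the `KNNBetaImputer` surface).

For a region (gene span ± 100 kb, inclusive), each CpG is regressed on
the trait with batch indicators and mean bisulfite conversion as
covariates; the per-CpG p-values are combined as T = −2 Σ ln pᵢ. The
region's empirical p compares T against B permutations of the trait
vector with methylation and covariates fixed:

    empirical_p = (1 + #{T_perm ≥ T_obs}) / (B + 1)

Conventions, fixed here because the procedure statement leaves them
open:

- **Add-one convention** guarantees a valid, nonzero p (minimum
  1/(B+1)).
- **One permutation matrix per region**, shared across that region's
  CpGs, so each permuted T is a valid joint draw.
- **Raw-permutation scheme**: the outcome is permuted raw and the
  covariates refit within each permutation (algebraically: the permuted
  trait is re-projected off the covariate span). The Freedman–Lane
  scheme, which permutes residuals and adds back fitted values, is
  available via `scheme="freedman_lane"`; under the null with fixed
  covariates the two coincide in distribution for this statistic.
- **p = 0 underflow**: per-CpG p-values are floored at 1e-300 before
  logging, with a warning — never silently inside `fisher_statistic`
  itself, which treats p = 0 as an error.
- **FDR universes**: the omnibus FDR is Benjamini–Hochberg across the
  candidate regions of a run; the per-CpG (top-CpG) FDR is computed
  across all CpGs tested in all candidate regions of the run. Both are
  decisions, not derivations, and are confined to one code path.

The correlation of CpG p-values within a region makes the χ²(2k)
reference for T invalid — which is exactly why the permutation null is
used; the χ² distribution appears only in tests of the statistic on
independent uniforms. Regions significant at FDR < 0.05 are rerun with
the lead SNP dosage and EV1–3 added to every per-CpG regression to
check that the epigenetic association is not driven by the genetic one.

## Stage 3: expression, and conditional models

Expression association is `trait ~ expression + RIN + log2(aligned
reads) + PMI + ribosomal bases`, on batch-adjusted FPKM values
(adjustment is upstream of this package; the simulator emits adjusted
values directly). Conditional secondary models add a single linear term
(TDP-43 stage 0–3 or severity 0–5 entered as ordinal scores — linear
coding keeps one coefficient and one df — or a second SNP's dosage) and
report attenuation = 1 − β_cond/β_marg; conditioning variables with
r² > 0.99 to the dosage are rejected as collinear.

## Variance ledger

Two nested OLS fits of *raw* last global cognition (not the residual):
base = demographics + pathologies; full = base + lead-SNP dosages +
top-CpG betas + RNA values of the candidate genes (top CpGs entered as
raw beta values, one per region — the simplest faithful coding;
configurable). The ledger reports both adjusted R² values, their
difference (which may be negative, since adjusted R² penalises
predictor count) and 1 − full adj R² as the unexplained share; the
unadjusted R² is asserted monotone from base to full.

## The synthetic cohort

What the generator emulates, and how:

- **Genotypes.** Haplotypes are Bernoulli(MAF) indicators thresholded
  from a latent AR(1) Gaussian process with lag-1 correlation
  `ld_decay` (Gaussian copula); the dosage is the haplotype sum, so
  adjacent-dosage correlation ≈ `ld_decay` attenuated by
  dichotomisation, decaying geometrically with distance. Per-variant
  empirical MAF ≥ 0.01 is enforced by redrawing an offending block (the
  default MAF range (0.05, 0.45) makes this essentially a no-op). A
  configurable fraction of variants (default 0.3) receives truncated
  Gaussian noise (sd 0.05) to emulate fractional imputed dosages.
  Subjects split 859:120-style across two platforms.
- **Pathologies.** A shared standard-normal frailty factor scales
  gamma-distributed regional counts (positively skewed, as pathology
  counts are) which are scaled and square-root-composited exactly as
  the analysis side expects; CAA grades are Binomial(4, ·) per region
  and averaged; ordinals are Binomial(3, ·); binaries Bernoulli; TDP-43
  stage comes from an ordinal (latent-logistic) model optionally linked
  to a designated variant, with severity derived from stage plus noise,
  and ~15% missingness.
- **Cognition.** Cognition proximate to death is a linear combination
  of the standardized base covariates, EV1–3 (small effects), the
  planted channel contributions and Gaussian noise. The base part is
  scaled so that demographics + pathology explain
  `pathology_effect_fraction` (default 0.41) of the variance; if
  `planted_variance_fraction` is set, the combined planted contribution
  is additionally rescaled to that share (used for
  parameter-recovery experiments at 0.41/0.06). SNP effects are per
  minor allele; CpG and RNA effects are per SD of the predictor. The
  17 tests are the latent trait plus test noise (sd 0.4), stored as raw
  scores against per-test baseline means/SDs; per-visit trajectories
  decline at a frailty-linked rate, giving baseline scores and slopes.
- **Methylation.** Per-CpG means are a Beta mixture (hypo-/hyper-/
  intermediate); subject effects live on the logit scale and share a
  regional factor (correlation 0.3 within a gene region — methylation
  is regionally correlated, and this is what makes a region-level
  omnibus test the right tool); batch (3 levels) and bisulfite
  conversion have small logit-scale effects; missingness is MCAR at 1%.
- **Expression.** Log-normal per-gene scales (overridable per gene — the
  study-default config pins the three planted genes to FPKM medians of
  1.6, 70 and 3.55 so effect sizes on the FPKM scale are meaningful),
  subject variation on the log scale, small technical-covariate
  effects; planted cis-eQTL effects are additive on the FPKM scale
  (clipped at 0) so the per-allele effect is directly recoverable.
- **Truth ledger.** Records every planted effect with its realized SD
  contribution, the realized base and planted variance fractions
  (computed by regressing the generated cognition on the actual
  covariates/predictors), and all linking choices.

What the generator does *not* emulate: realistic haplotype reference
panels, population structure (EV1–3 are plain standard normals whose
only role is covariate plumbing), array-specific probe artifacts,
cell-type composition, informative missingness. Consequently, passing
tests demonstrate the *procedures* are correct and calibrated under the
assumed generating model — not that the pipeline is robust to
confounding structures the generator does not produce.

### Study-scale defaults

`SimConfig.study_defaults()` plants three loci echoing the reported
convergence structure: G1, a deleterious low-MAF locus (SNP −0.42 per
allele at MAF 0.07, CpG −0.12 SD, RNA −0.11 SD); G2, protective
(SNP +0.30 at MAF 0.11, CpG +0.12 SD, RNA +0.23 SD); G3, a common
allele (SNP +0.19 at MAF 0.41) that also lowers TDP-43 stage and its
own expression (eQTL −0.22/allele) but has no methylation or RNA effect
on the trait — the "genetic-only" pattern. At n = 979 each SNP has
roughly 40–70% power at p < 1e-5, so which loci surface varies by seed;
this is the honest operating regime of a suggestive-threshold design,
and the multistep follow-up (not the scan alone) is what produces
reliable convergence calls. The per-SD CpG and RNA effect sizes were
derived once from the scale of the reported associations
(top-CpG z-scores ≈ 3 at n = 648; RNA effects of −0.40 and +0.0064 on
FPKM scales with SDs of roughly 0.27 and 36).

## Numerical choices

- All single-predictor models run through one exact closed-form partial
  regression (Frisch–Waugh–Lovell: residualise predictor and outcome on
  the covariate block via QR, simple regression on residuals with the
  full model's df). This is bit-identical to a full OLS refit and lets
  a scan or a permutation batch run as matrix products; equality with
  statsmodels OLS is asserted in tests at 1e-10.
- Exact fits (zero residual) floor the SE at the smallest positive
  float rather than reporting 0.
- p-values are clipped into (0, 1] at the smallest positive float.
- Degenerate inputs error loudly: monomorphic dosages, constant CpGs or
  expression, all-missing subjects, B ≤ 0 (B < 100 warns).
- All randomness descends from one root seed through
  `numpy.random.SeedSequence.spawn`, one stream per stage and per
  region, so stages are independently reproducible and re-runs are
  bit-identical.

## Problem sizes in the test-suite experiments

Calibration experiments use 2,000 null replicates at n = 150 for the
three association tests and 500 null regions (n = 100, 8 CpGs, B = 200)
for the omnibus; end-to-end convergence uses 50 seeded runs at
n = 2,000 with B = 1,000 and a planted gene (SNP 0.3/allele, CpG 0.2 SD,
RNA 0.2 SD), and 10 null runs. These sizes give the Monte-Carlo
intervals stated in the tests while keeping the default `pytest` run
around a minute. The acceptance script runs the study-scale cohort
(n = 979) with the full B = 10,000 permutations.

## Known limitations

- Meta-analysis reports no heterogeneity statistics (two platforms,
  fixed-effect only).
- The omnibus test permutes the outcome raw; with strong confounding by
  the technical covariates the Freedman–Lane option is the better
  calibrated choice.
- Mixed-model decline slopes are replaced by per-subject OLS slopes.
- The two-platform split assigns subjects deterministically by index,
  not by any population structure.
- Secondary-phenotype regressions (depression, imaging, synaptic
  proteins) are out of scope; `conditional_association` with a custom
  covariate list is the supported route to such analyses.
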