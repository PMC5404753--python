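"""Stage-2 machinery: kNN imputation, region selection, Fisher
combination, permutation omnibus, BH-FDR."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from residcog import (
    bh_fdr,
    cpg_association,
    fisher_statistic,
    knn_impute,
    omnibus_adjusted,
    omnibus_test,
    region_cpgs,
)
from residcog.datatypes import MethylationSet
from residcog.methylation import MethylationOmnibus


def _meth(betas, rng, chrom="1", positions=None):
    n, m = betas.shape
    if positions is None:
        positions = np.arange(m) * 500 + 950_000
    cpg_map = pd.DataFrame(
        {"cpg_id": [f"cg{j:03d}" for j in range(m)], "chrom": chrom, "pos": positions}
    )
    return MethylationSet(
        [f"S{i}" for i in range(n)], cpg_map, betas,
        rng.choice(["b1", "b2"], n), rng.normal(90, 2, n),
    )


# --- kNN imputation ---------------------------------------------------------

def test_impute_identity_when_complete(rng):
    betas = rng.uniform(0, 1, (30, 8))
    ms = _meth(betas, rng)
    out = knn_impute(ms, k=5)
    np.testing.assert_array_equal(out.betas, betas)


def test_impute_constant_neighbourhood(rng):
    betas = np.full((25, 4), 0.7)
    betas[0, 2] = np.nan
    ms = _meth(betas, rng)
    out = knn_impute(ms, k=100)  # k capped at available subjects
    assert out.betas[0, 2] == pytest.approx(0.7)
    assert not np.isnan(out.betas).any()


def test_impute_beats_column_mean_on_masked_data():
    """Mask-and-recover: kNN exploits inter-subject similarity that the
    column mean ignores."""
    wins = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        n, m = 120, 30
        latent = r.normal(0, 1, (n, 1))
        logits = latent + r.normal(0, 0.5, (n, m))
        truth = 1 / (1 + np.exp(-logits))
        mask = r.random((n, m)) < 0.05
        mask[mask.all(axis=1), 0] = False
        obs = truth.copy()
        obs[mask] = np.nan
        ms = _meth(obs, r)
        rec = knn_impute(ms, k=10).betas
        rmse_knn = np.sqrt(np.mean((rec[mask] - truth[mask]) ** 2))
        col_mean = np.nanmean(obs, axis=0)
        rmse_mean = np.sqrt(np.mean((np.broadcast_to(col_mean, obs.shape)[mask] - truth[mask]) ** 2))
        wins += rmse_knn < rmse_mean
    assert wins >= 15


def test_impute_all_missing_subject_errors(rng):
    betas = rng.uniform(0, 1, (10, 4))
    betas[3, :] = np.nan
    with pytest.raises(ValueError, match="all CpGs missing"):
        knn_impute(_meth(betas, rng), k=3)


# --- region selection -------------------------------------------------------

def test_region_boundaries_inclusive():
    gene = pd.Series({"gene_id": "G", "chrom": "1", "start": 1_000_000, "end": 1_050_000})
    cpgs = pd.DataFrame(
        {"cpg_id": ["at_start", "at_edge", "past_edge", "other_chrom"],
         "chrom": ["1", "1", "1", "2"],
         "pos": [1_000_000, 1_150_000, 1_150_001, 1_000_000]}
    )
    ids = region_cpgs(gene, cpgs)
    assert ids == ["at_start", "at_edge"]


def test_region_count_on_constructed_fixture(rng):
    gene = pd.Series({"gene_id": "G", "chrom": "7", "start": 500_000, "end": 540_000})
    inside = rng.integers(400_000, 640_001, 44)
    outside = np.concatenate([rng.integers(1, 399_000, 30), rng.integers(641_000, 900_000, 30)])
    cpgs = pd.DataFrame(
        {"cpg_id": [f"c{j}" for j in range(104)], "chrom": "7",
         "pos": np.concatenate([inside, outside])}
    )
    assert len(region_cpgs(gene, cpgs)) == 44


def test_region_matches_interval_scan_oracle(rng):
    for _ in range(20):
        start = int(rng.integers(1, 5_000_000))
        end = start + int(rng.integers(1, 200_000))
        gene = pd.Series({"gene_id": "G", "chrom": "3", "start": start, "end": end})
        pos = rng.integers(1, 6_000_000, 200)
        cpgs = pd.DataFrame({"cpg_id": [f"c{j}" for j in range(200)], "chrom": "3", "pos": pos})
        oracle = [f"c{j}" for j in range(200)
                  if start - 100_000 <= pos[j] <= end + 100_000]
        assert region_cpgs(gene, cpgs) == oracle


# --- per-CpG regression -----------------------------------------------------

def test_cpg_association_matches_statsmodels(rng):
    n = 120
    beta = rng.uniform(0.2, 0.8, n)
    tech = rng.normal(0, 1, (n, 2))
    y = 1.5 * beta + tech @ [0.2, -0.1] + rng.normal(0, 1, n)
    est, se, p = cpg_association(beta, y, tech)
    ref = sm.OLS(y, sm.add_constant(np.column_stack([tech, beta]))).fit()
    assert est == pytest.approx(ref.params[-1], abs=1e-10)
    assert p == pytest.approx(ref.pvalues[-1], rel=1e-8)


def test_cpg_association_exact_and_degenerate(rng):
    beta = rng.uniform(0, 1, 100)
    _, _, p = cpg_association(beta, 3 * beta)
    assert p < 1e-100
    with pytest.raises(ValueError, match="constant"):
        cpg_association(np.full(100, 0.5), rng.normal(0, 1, 100))


def test_cpg_association_power_at_study_scale(rng):
    """Standardized effect 0.15 at n=648 is detected with power > 0.8."""
    n, hits, reps = 648, 0, 200
    for _ in range(reps):
        x = rng.uniform(0, 1, n)
        xs = (x - x.mean()) / x.std()
        y = 0.15 * xs + rng.normal(0, 1, n)
        _, _, p = cpg_association(x, y)
        hits += p < 0.05
    assert hits / reps > 0.8


# --- Fisher statistic and BH-FDR -------------------------------------------

def test_fisher_examples_and_errors():
    assert fisher_statistic([1, 1, 1]) == pytest.approx(0.0)
    assert fisher_statistic([0.1, 0.01]) == pytest.approx(13.8155, abs=1e-4)
    with pytest.raises(ValueError):
        fisher_statistic([])
    with pytest.raises(ValueError):
        fisher_statistic([0.5, 0.0])


def test_fisher_matches_scipy_and_is_permutation_invariant(rng):
    p = rng.uniform(0.001, 1, 12)
    ours = fisher_statistic(p)
    ref = sps.combine_pvalues(p, method="fisher").statistic
    assert ours == pytest.approx(ref, rel=1e-12)
    assert fisher_statistic(p[::-1]) == pytest.approx(ours)
    q = p.copy()
    q[3] *= 0.5  # decreasing any p strictly increases T
    assert fisher_statistic(q) > ours


def test_fisher_null_distribution_is_chi2(rng):
    k = 6
    draws = -2 * np.log(rng.uniform(size=(10_000, k))).sum(axis=1)
    assert np.mean(draws) == pytest.approx(2 * k, rel=0.05)


def test_bh_fdr_examples_and_oracle(rng):
    np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_fdr([0.42]), [0.42])
    for _ in range(20):
        p = rng.uniform(0, 1, int(rng.integers(1, 40)))
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), oracle, atol=1e-12)


# --- omnibus test -----------------------------------------------------------

def test_omnibus_extreme_signal_floors_at_add_one(rng):
    n, B = 150, 200
    beta = rng.uniform(0.2, 0.8, (n, 5))
    y = 5 * beta[:, 0] + rng.normal(0, 0.1, n)
    gene = pd.Series({"gene_id": "G", "chrom": "1", "start": 949_000, "end": 953_000})
    ms = _meth(beta, rng)
    res = omnibus_test(gene, ms, y, B=B, seed=3)
    assert res.empirical_p == pytest.approx(1 / (B + 1))
    assert res.observed_T == pytest.approx(-2 * np.log(res.cpg_p_values).sum())


def test_omnibus_guards_on_B(rng):
    beta = rng.uniform(0, 1, (60, 3))
    gene = pd.Series({"gene_id": "G", "chrom": "1", "start": 949_000, "end": 953_000})
    ms = _meth(beta, rng)
    y = rng.normal(0, 1, 60)
    with pytest.raises(ValueError):
        omnibus_test(gene, ms, y, B=0)
    with pytest.warns(UserWarning, match="permutations"):
        omnibus_test(gene, ms, y, B=50, seed=1)


def test_omnibus_no_cpgs_in_region_errors(rng):
    beta = rng.uniform(0, 1, (60, 3))
    ms = _meth(beta, rng)
    gene = pd.Series({"gene_id": "G", "chrom": "9", "start": 1, "end": 10})
    with pytest.raises(ValueError, match="no CpGs"):
        omnibus_test(gene, ms, rng.normal(0, 1, 60), B=200)


def test_omnibus_invariant_to_relabeling_and_trait_shift(rng):
    n = 80
    beta = rng.uniform(0, 1, (n, 4))
    y = rng.normal(0, 1, n)
    gene = pd.Series({"gene_id": "G", "chrom": "1", "start": 949_000, "end": 953_000})
    ms = _meth(beta, rng)
    base = omnibus_test(gene, ms, y, B=300, seed=11)
    shifted = omnibus_test(gene, ms, y + 7.5, B=300, seed=11)
    assert shifted.empirical_p == base.empirical_p
    assert shifted.observed_T == pytest.approx(base.observed_T, rel=1e-9)
    perm = np.random.default_rng(0).permutation(n)
    ms2 = MethylationSet([f"S{i}" for i in range(n)], ms.cpg_map, beta[perm],
                         ms.batch[perm], ms.bisulfite_conversion[perm])
    relabeled = omnibus_test(gene, ms2, y[perm], B=300, seed=11)
    assert relabeled.observed_T == pytest.approx(base.observed_T, rel=1e-9)


def test_omnibus_single_cpg_matches_exhaustive_permutation(rng):
    """At one CpG and tiny n, the empirical p converges to the exact
    (enumerated) permutation p of the regression statistic."""
    n = 7
    beta = rng.uniform(0.1, 0.9, (n, 1))
    y = rng.normal(0, 1, n)
    x = beta[:, 0]
    xc = x - x.mean()

    def abs_corr(v):
        vc = v - v.mean()
        return abs(xc @ vc) / np.sqrt((xc @ xc) * (vc @ vc))

    obs = abs_corr(y)
    import math

    hits = sum(abs_corr(np.asarray(p)) >= obs - 1e-12
               for p in itertools.permutations(y))
    exact = hits / math.factorial(n)
    gene = pd.Series({"gene_id": "G", "chrom": "1", "start": 949_500, "end": 950_500})
    ms = _meth(beta, rng)
    res = omnibus_test(gene, ms, y, tech=np.zeros((n, 0)), B=20_000, seed=5)
    assert abs(res.empirical_p - exact) <= 0.01


def test_omnibus_power_with_one_planted_cpg():
    """Planted standardized effect 0.2 at one of 40 CpGs, n=648: the
    region is detected (empirical p < 0.05) in >= 80% of seeds."""
    hits, seeds = 0, 25
    gene = pd.Series({"gene_id": "G", "chrom": "1", "start": 940_000, "end": 980_000})
    for s in range(seeds):
        r = np.random.default_rng(1000 + s)
        n, m = 648, 40
        beta = r.uniform(0.1, 0.9, (n, m))
        xs = (beta[:, 7] - beta[:, 7].mean()) / beta[:, 7].std()
        y = 0.2 * xs + r.normal(0, 1, n)
        ms = _meth(beta, r)
        res = omnibus_test(gene, ms, y, B=500, seed=r)
        hits += res.empirical_p < 0.05
    assert hits / seeds >= 0.8


def test_adjusted_omnibus_orthogonal_snp_changes_little(rng):
    n = 200
    beta = rng.uniform(0.1, 0.9, (n, 5))
    y = 0.8 * beta[:, 0] + rng.normal(0, 1, n)
    d_raw = rng.binomial(2, 0.3, n).astype(float)
    # orthogonalize dosage in-sample against trait and all CpGs
    A = np.column_stack([np.ones(n), y, beta])
    d = d_raw - A @ np.linalg.lstsq(A, d_raw, rcond=None)[0]
    ev = rng.normal(0, 1, (n, 3))
    ev = ev - A @ np.linalg.lstsq(A, ev, rcond=None)[0]
    gene = pd.Series({"gene_id": "G", "chrom": "1", "start": 949_000, "end": 953_000})
    ms = _meth(beta, rng)
    tech = np.zeros((n, 0))
    base = omnibus_test(gene, ms, y, tech=tech, B=500, seed=9)
    adj = omnibus_adjusted(gene, ms, y, d, ev, tech=tech, B=500, seed=9)
    assert adj.observed_T == pytest.approx(base.observed_T, rel=0.05)
    assert abs(adj.empirical_p - base.empirical_p) < 0.05


def test_adjusted_omnibus_removes_snp_mediated_signal(rng):
    n = 300
    d = rng.binomial(2, 0.4, n).astype(float)
    # CpGs driven by the SNP; trait driven by the SNP only
    beta = np.clip(0.3 + 0.15 * d[:, None] + rng.normal(0, 0.02, (n, 4)), 0, 1)
    y = 0.5 * d + rng.normal(0, 0.5, n)
    ev = rng.normal(0, 1, (n, 3))
    gene = pd.Series({"gene_id": "G", "chrom": "1", "start": 949_000, "end": 953_000})
    ms = _meth(beta, rng)
    tech = np.zeros((n, 0))
    base = omnibus_test(gene, ms, y, tech=tech, B=500, seed=2)
    adj = omnibus_adjusted(gene, ms, y, d, ev, tech=tech, B=500, seed=2)
    assert base.empirical_p < 0.05
    assert adj.empirical_p > base.empirical_p * 5


def test_omnibus_estimator_fdr_across_regions(rng):
    n = 150
    m = 6
    beta = rng.uniform(0.1, 0.9, (n, 3 * m))
    y = 1.0 * beta[:, 2] + rng.normal(0, 1, n)
    positions = np.concatenate(
        [np.arange(m) * 300 + 1_000_000, np.arange(m) * 300 + 5_000_000,
         np.arange(m) * 300 + 9_000_000]
    )
    ms = _meth(beta, rng, positions=positions)
    genes = pd.DataFrame(
        {"gene_id": ["Ga", "Gb", "Gc"], "chrom": "1",
         "start": [1_000_000, 5_000_000, 9_000_000],
         "end": [1_001_500, 5_001_500, 9_001_500], "strand": "+"}
    )
    est = MethylationOmnibus(B=300, seed=7).fit(genes, ms, y)
    t = est.table_
    assert len(t) == 3
    np.testing.assert_allclose(np.sort(t["fdr_q"]),
                               np.sort(bh_fdr(t["empirical_p"])), atol=1e-12)
    est2 = MethylationOmnibus(B=300, seed=7).fit(genes, ms, y)
    pd.testing.assert_frame_equal(est.table_, est2.table_)
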