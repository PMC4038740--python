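"""Genotype-calling stage: normalization, per-SNP PCA, EM, cohort QC."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedmap import caller as cl
from breedmap.containers import MISSING, GenotypeMatrix, IntensityMatrix
from breedmap.simulate import IntensityModel, SimulationConfig, simulate_dataset

from conftest import make_genotype_matrix


def _intensity_fixture(vectors, chips):
    """IntensityMatrix from per-sample pooled value vectors (len = 2*n_snps)."""
    vectors = np.asarray(vectors, dtype=float)
    n_s, n_vals = vectors.shape
    n_snps = n_vals // 2
    samples = pd.DataFrame({"sample": [f"s{i}" for i in range(n_s)],
                            "chip": list(chips)})
    snps = pd.DataFrame({"id": [f"v{j}" for j in range(n_snps)],
                         "chrom": "chr1", "pos": np.arange(n_snps) * 1000,
                         "ref": "A", "alt": "B"})
    return IntensityMatrix(vectors.reshape(n_s, n_snps, 2), snps, samples)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def test_quantile_normalization_rank_mean_oracle():
    # hand oracle: sorted means (1+10)/2, ..., (6+60)/2
    intens = _intensity_fixture([[1, 2, 3, 4, 5, 6],
                                 [10, 20, 30, 40, 50, 60]], ["c1", "c1"])
    out = cl.quantile_normalize_per_chip(intens)
    expected = np.array([5.5, 11.0, 16.5, 22.0, 27.5, 33.0])
    for i in range(2):
        assert np.allclose(out.values[i].reshape(-1), expected)


def test_quantile_normalization_fixed_point_on_identical_distributions():
    # permuted copies of the same value multiset: output equals input
    v1 = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
    v2 = v1[::-1].copy()
    intens = _intensity_fixture([v1, v2], ["c1", "c1"])
    out = cl.quantile_normalize_per_chip(intens)
    assert np.allclose(out.values, intens.values)


def test_rank_match_invariant_to_monotone_transform():
    # the rank-matching step depends on a vector only through its ranks
    profile = np.sort(np.array([0.3, 1.0, 2.0, 5.0, 7.0, 11.0]))
    v = np.array([2.0, 0.1, 5.0, 3.3, 8.0, 1.1])
    assert np.allclose(cl._rank_match(v, profile),
                       cl._rank_match(np.exp(v), profile))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_quantile_normalization_preserves_within_sample_ranks(seed):
    rng = np.random.default_rng(seed)
    vectors = rng.gamma(2.0, 1.0, size=(4, 12))
    intens = _intensity_fixture(vectors, ["c1", "c1", "c2", "c2"])
    out = cl.quantile_normalize_per_chip(intens)
    for i in range(4):
        a = intens.values[i].reshape(-1)
        b = out.values[i].reshape(-1)
        ai = np.argsort(a, kind="stable")
        assert (np.diff(b[ai]) >= -1e-12).all()


def test_single_sample_chip_passes_through_with_warning():
    intens = _intensity_fixture([[1, 2, 3, 4, 5, 6]], ["c1"])
    with pytest.warns(UserWarning, match="single sample"):
        out = cl.quantile_normalize_per_chip(intens)
    assert np.allclose(out.values, intens.values)


# ---------------------------------------------------------------------------
# per-SNP PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_geometry_on_antidiagonal_line():
    t = np.linspace(-1, 1, 20)
    xy = np.stack([t, -t], axis=1) + 5.0
    res = cl.snp_pca(xy)
    assert res.explained[0] > 1 - 1e-12
    assert not res.flagged


def test_pca_orientation_follows_a_channel():
    rng = np.random.default_rng(0)
    xy = rng.normal(size=(200, 2)) * [3.0, 0.5]
    res = cl.snp_pca(xy)
    assert np.corrcoef(res.scores[:, 0], xy[:, 0])[0, 1] > 0


def test_pca_rotation_equivariance():
    rng = np.random.default_rng(1)
    xy = rng.normal(size=(100, 2)) * [2.0, 0.4] + [3.0, 1.0]
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    r1 = cl.snp_pca(xy)
    r2 = cl.snp_pca(xy @ rot.T)
    for pc in (0, 1):
        assert (np.allclose(r1.scores[:, pc], r2.scores[:, pc], atol=1e-8)
                or np.allclose(r1.scores[:, pc], -r2.scores[:, pc], atol=1e-8))


def test_pca_isotropic_cloud_splits_variance_evenly():
    rng = np.random.default_rng(2)
    res = cl.snp_pca(rng.normal(size=(10_000, 2)))
    assert abs(res.explained[0] - 0.5) < 0.05


def test_pca_zero_variance_cloud_flagged():
    res = cl.snp_pca(np.ones((10, 2)))
    assert res.flagged
    assert np.allclose(res.scores, 0.0)


# ---------------------------------------------------------------------------
# EM t-mixture calling
# ---------------------------------------------------------------------------

def _three_cluster_scores(rng, n=300, sep=6.0, weights=(0.3, 0.4, 0.3)):
    truth = rng.choice(3, size=n, p=weights)
    centers = np.array([[-sep, 0.0], [0.0, 0.0], [sep, 0.0]])
    return centers[truth] + rng.normal(scale=1.0, size=(n, 2)), truth


def test_em_recovers_well_separated_clusters():
    rng = np.random.default_rng(3)
    scores, truth = _three_cluster_scores(rng)
    geno, conf, fit = cl.em_t_mixture_call(scores, seed=0)
    called = geno != MISSING
    # PC1 sorted descending maps to dosage 0..2; truth cluster 2 has top PC1
    agree = (geno[called] == (2 - truth)[called]).mean()
    assert agree >= 0.99
    assert called.mean() > 0.9


def test_em_loglik_is_monotone_nondecreasing():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        scores, _ = _three_cluster_scores(rng, n=150, sep=4.0)
        fit = cl.fit_t_mixture(scores, k=3, df=5.0, max_iter=100, tol=0.0,
                               seed=seed)
        ll = np.array(fit.loglik)
        assert (np.diff(ll) >= -1e-8 * np.abs(ll[:-1])).all()


def test_em_mixture_weights_sum_to_one():
    rng = np.random.default_rng(4)
    scores, _ = _three_cluster_scores(rng)
    fit = cl.fit_t_mixture(scores, seed=0)
    assert abs(fit.weights.sum() - 1.0) < 1e-9


def test_monomorphic_snp_called_majority_or_flagged():
    cfg = SimulationConfig(
        seed=5, n_snps=40, n_breeds=2, n_per_breed=40, missing_rate=0.0,
        planted_assoc=(),
        intensity_model=IntensityModel(chip_factors=(1.0,)))
    ds = simulate_dataset(cfg)
    # force one SNP monomorphic in truth, regenerate intensities
    truth = ds.truth_genotypes
    truth.genotypes[:, 0] = 0
    from breedmap.simulate import simulate_intensities
    intens = simulate_intensities(truth, cfg)
    cs = cl.call_genotypes(intens)
    g = cs.genotypes[:, 0]
    called = g != MISSING
    majority_ok = called.any() and (g[called] == 0).mean() >= 0.95
    assert majority_ok or cs.params[0]["flagged"]


def test_calls_invariant_to_chip_scaling():
    base = SimulationConfig(
        seed=6, n_snps=60, n_breeds=2, n_per_breed=30,
        intensity_model=IntensityModel(noise_scale=0.13,
                                       chip_factors=(1.0, 1.0)))
    scaled = dataclasses.replace(
        base, intensity_model=IntensityModel(noise_scale=0.13,
                                             chip_factors=(2.0, 0.5)))
    ds1 = simulate_dataset(base)
    ds2 = simulate_dataset(scaled)
    cs1 = cl.call_genotypes(ds1.intensities)
    cs2 = cl.call_genotypes(ds2.intensities)
    assert np.array_equal(cs1.genotypes, cs2.genotypes)


# ---------------------------------------------------------------------------
# cohort QC
# ---------------------------------------------------------------------------

def _qc_fixture():
    """20 SNPs x 20 samples with hand-planned removals.

    SNP 0: missing in 3 samples -> call rate 0.85 <= 0.9 -> removed (step 1).
    Sample 0: missing at SNPs 1-15 -> 4/19 = 0.21 <= 0.25 on the surviving
    SNPs -> removed (step 2).
    SNP 16: one alt allele among the 19 remaining samples -> MAF 0.026 <=
    0.05 -> removed (step 3). Everything else is common and well called.
    """
    col = np.array([0, 1, 1, 2] * 5, dtype=np.int8).reshape(20, 1)
    geno = np.tile(col, (1, 20))   # every SNP: alt freq 0.5 down samples
    geno[17:20, 0] = MISSING       # SNP0: 17/20 = 0.85
    geno[0, 1:16] = MISSING        # sample0: 15 missing
    geno[:, 16] = 0
    geno[1, 16] = 1                # after sample0 removal: 1/38 alleles
    return geno


def test_qc_filter_matches_manual_oracle():
    geno = _qc_fixture()
    gm = make_genotype_matrix(geno)
    out, report = cl.qc_filter(gm)

    # independent manual oracle, step by step
    g = geno.copy()
    snp_keep = (g != MISSING).mean(axis=0) > 0.9
    ids = np.array([f"v{j}" for j in range(20)])[~snp_keep]
    g = g[:, snp_keep]
    sample_keep = (g != MISSING).mean(axis=1) > 0.25
    g = g[sample_keep]
    freq = np.array([r[r != MISSING].mean() / 2 for r in g.T])
    g = g[:, np.minimum(freq, 1 - freq) > 0.05]

    assert np.array_equal(out.genotypes, g)
    assert set(ids) == {"v0"}
    removed_snps = set(report.loc[report["kind"] == "snp", "id"])
    assert removed_snps == {"v0", "v16"}
    removed_samples = set(report.loc[report["kind"] == "sample", "id"])
    assert removed_samples == {"s0"}


def test_qc_filter_order_is_snp_sample_maf():
    # sample0 survives only because low-call-rate SNPs are removed first;
    # a sample-first ordering would have removed it (2/10 = 0.2 <= 0.25)
    col = np.array([0, 1, 1, 2] * 5, dtype=np.int8).reshape(20, 1)
    geno = np.tile(col, (1, 10))
    geno[:16, :5] = MISSING        # SNPs 0-4: call rate 0.2 -> removed
    geno[0, :8] = MISSING          # sample0: 2/10 called overall
    gm = make_genotype_matrix(geno)
    out, report = cl.qc_filter(gm)
    # after the SNP step sample0 is called at 2/5 = 0.4 > 0.25 and stays
    assert "s0" in set(out.samples["sample"])
    assert out.genotypes.shape == (20, 5)
    assert not (report["kind"] == "sample").any()


def test_qc_filter_removes_low_maf_after_sample_filtering():
    geno = np.zeros((10, 2), dtype=np.int8)
    geno[:, 0] = [0, 0, 0, 0, 0, 0, 0, 0, 1, 1]   # maf 0.1 kept
    geno[0, 1] = 1                                 # maf 0.05 removed
    gm = make_genotype_matrix(geno)
    out, report = cl.qc_filter(gm)
    assert list(out.snps["id"]) == ["v0"]
    assert report.iloc[0]["reason"] == "maf"


def test_qc_filter_everything_missing_raises():
    geno = np.full((3, 4), MISSING, dtype=np.int8)
    gm = make_genotype_matrix(geno)
    with pytest.raises(ValueError, match="QC removed"):
        cl.qc_filter(gm)


def test_concordance_counts_only_called_genotypes():
    truth = make_genotype_matrix(np.array([[0, 1, 2, 1]], dtype=np.int8))
    calls = make_genotype_matrix(np.array([[0, MISSING, 2, 0]], dtype=np.int8))
    res = cl.concordance(calls, truth)
    assert res["n_called"] == 3
    assert res["concordance"] == pytest.approx(2 / 3)
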