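"""Case-only classification, burden, candidate selection and contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedmap import burden as bd
from breedmap.containers import MISSING, BreedPanel


def _dogs(case=("c1", "c2"), ctrl=("k1", "k2"), breeds=None):
    names = list(case) + list(ctrl)
    if breeds is None:
        breeds = ["b1"] * len(names)
    return pd.DataFrame({"sample": names,
                         "breed": breeds,
                         "group": ["case"] * len(case) + ["control"] * len(ctrl)})


def _variant(pos, gts, consequence="noncoding", constrained=False,
             gene="", vclass="SNP", chrom="chr1"):
    row = {"chrom": chrom, "pos": pos, "ref": "A", "alt": "T",
           "vclass": vclass, "consequence": consequence,
           "constrained": constrained, "gene": gene}
    row.update(gts)
    return row


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_status_assignment_rules():
    dogs = _dogs()
    table = pd.DataFrame([
        _variant(100, {"c1": 1, "c2": 2, "k1": 0, "k2": 0}),   # case-only
        _variant(200, {"c1": 1, "c2": 0, "k1": 1, "k2": 0}),   # shared
        _variant(300, {"c1": 0, "c2": 0, "k1": 2, "k2": 0}),   # control-only
        _variant(400, {"c1": 1, "c2": 0, "k1": MISSING, "k2": 0}),  # priv-miss
        _variant(500, {"c1": 0, "c2": 0, "k1": 0, "k2": 0}),   # no carriers
    ])
    out = bd.classify_variants(table, dogs)
    assert list(out["status"]) == ["case-only", "shared", "control-only",
                                   "private-missing", "shared"]


def test_status_partition_is_exhaustive():
    rng = np.random.default_rng(0)
    dogs = _dogs(case=tuple(f"c{i}" for i in range(4)),
                 ctrl=tuple(f"k{i}" for i in range(4)))
    rows = []
    for v in range(200):
        gts = {d: int(g) for d, g in zip(
            dogs["sample"], rng.choice([MISSING, 0, 1, 2], size=8,
                                       p=[0.1, 0.5, 0.3, 0.1]))}
        rows.append(_variant(v * 10, gts))
    out = bd.classify_variants(pd.DataFrame(rows), dogs)
    counts = out["status"].value_counts()
    assert counts.sum() == len(out)
    assert set(counts.index) <= {"case-only", "control-only", "shared",
                                 "private-missing"}
    case_only = out[out["status"] == "case-only"]
    assert (case_only["ctrl_carriers"] == 0).all()
    assert (case_only["case_carriers"] >= 1).all()
    assert (case_only["ctrl_call_rate"] >= 1.0).all()


def test_all_missing_variant_excluded():
    dogs = _dogs()
    table = pd.DataFrame([
        _variant(100, {"c1": MISSING, "c2": MISSING,
                       "k1": MISSING, "k2": MISSING}),
        _variant(200, {"c1": 1, "c2": 0, "k1": 0, "k2": 0}),
    ])
    out = bd.classify_variants(table, dogs)
    assert len(out) == 1 and out["pos"].iloc[0] == 200


def test_relaxed_control_callrate_promotes_private_missing():
    dogs = _dogs()
    table = pd.DataFrame([
        _variant(100, {"c1": 1, "c2": 0, "k1": MISSING, "k2": 0}),
    ])
    strict = bd.classify_variants(table, dogs, control_callrate_min=1.0)
    relaxed = bd.classify_variants(table, dogs, control_callrate_min=0.5)
    assert strict["status"].iloc[0] == "private-missing"
    assert relaxed["status"].iloc[0] == "case-only"


def test_classifier_recovers_planted_truth(dataset):
    out = bd.classify_variants(dataset.variant_table, dataset.seq_dogs)
    truth = dataset.variant_truth
    merged = out.merge(truth, on="pos", suffixes=("", "_t"))
    planted = merged[merged["planted_status"].isin(["case-only",
                                                    "control-only"])]
    assert (planted["status"] == planted["planted_status"]).all()


# ---------------------------------------------------------------------------
# constrained-element intersection
# ---------------------------------------------------------------------------

def test_constrained_intersection_half_open():
    bed = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
    dogs = _dogs()
    table = pd.DataFrame([
        _variant(100, {"c1": 1, "c2": 0, "k1": 0, "k2": 0}),   # at start: in
        _variant(199, {"c1": 1, "c2": 0, "k1": 0, "k2": 0}),   # last base: in
        _variant(200, {"c1": 1, "c2": 0, "k1": 0, "k2": 0}),   # at end: out
    ])
    out = bd.intersect_constrained(table, bed)
    assert list(out["constrained"]) == [True, True, False]


@pytest.mark.parametrize("seed", range(5))
def test_constrained_intersection_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, 1_000_000, size=30)
    bed = pd.DataFrame({"chrom": "chr1", "start": starts,
                        "end": starts + rng.integers(50, 5000, size=30)})
    dogs = _dogs()
    rows = [_variant(int(p), {"c1": 1, "c2": 0, "k1": 0, "k2": 0})
            for p in rng.integers(0, 1_005_000, size=200)]
    out = bd.intersect_constrained(pd.DataFrame(rows), bed)
    for _, r in out.iterrows():
        expected = bool(((bed["start"] <= r["pos"])
                         & (r["pos"] < bed["end"])).any())
        assert bool(r["constrained"]) == expected


def test_malformed_bed_line_reports_line_number(tmp_path):
    from breedmap.io import read_bed
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t10\t20\nchr1\toops\t30\n")
    with pytest.raises(ValueError, match="line 2"):
        read_bed(bad)


# ---------------------------------------------------------------------------
# per-dog counts and rank-sum test
# ---------------------------------------------------------------------------

def exact_rank_sum_p(x, y):
    """Two-sided exact rank-sum P by full enumeration of group labelings."""
    pooled = np.concatenate([x, y])
    n = len(x)
    obs = float(np.sum(x))
    stats_all = []
    for idx in itertools.combinations(range(len(pooled)), n):
        stats_all.append(float(pooled[list(idx)].sum()))
    stats_all = np.array(stats_all)
    # two-sided: deviation of the group sum from its permutation mean
    dev = abs(obs - stats_all.mean())
    p = (np.abs(stats_all - stats_all.mean()) >= dev - 1e-12).mean()
    return p


def test_rank_sum_exact_p_on_separated_counts():
    x, y = [15, 15, 16, 14], [4, 3, 4, 5]
    stat, p = bd.rank_sum_test(x, y)
    assert p == pytest.approx(2 / 70)
    assert p == pytest.approx(exact_rank_sum_p(np.array(x, float),
                                               np.array(y, float)))


def test_rank_sum_identical_vectors_p_one():
    _, p = bd.rank_sum_test([4, 4, 4], [4, 4, 4])
    assert p == pytest.approx(1.0)


def test_rank_sum_requires_two_per_group():
    with pytest.raises(ValueError):
        bd.rank_sum_test([1], [2, 3])


def _burden_table():
    dogs = _dogs(case=("c1", "c2", "c3"), ctrl=("k1", "k2", "k3"),
                 breeds=["b1", "b1", "b2", "b1", "b2", "b2"])
    rows = []
    # case-only constrained variants carried by specific dogs
    rows.append(_variant(1000, {"c1": 1, "c2": 1, "c3": 0,
                                "k1": 0, "k2": 0, "k3": 0},
                         constrained=True, gene="GA"))
    rows.append(_variant(2000, {"c1": 1, "c2": 0, "c3": 1,
                                "k1": 0, "k2": 0, "k3": 0},
                         constrained=True, consequence="missense", gene="GA"))
    rows.append(_variant(3000, {"c1": 0, "c2": 0, "c3": 0,
                                "k1": 1, "k2": 1, "k3": 0},
                         constrained=True, gene="GA"))
    rows.append(_variant(4000, {"c1": 1, "c2": 1, "c3": 1,
                                "k1": 1, "k2": 0, "k3": 0}))
    return pd.DataFrame(rows), dogs


def test_per_dog_count_test_counts_carriers():
    table, dogs = _burden_table()
    table = bd.classify_variants(table, dogs)
    res = bd.per_dog_count_test(table, dogs, constrained_only=True)
    assert res["case_counts"].tolist() == [2, 1, 1]
    assert res["control_counts"].tolist() == [1, 1, 0]


def test_per_dog_exclusions_honored():
    table, dogs = _burden_table()
    table = bd.classify_variants(table, dogs)
    res = bd.per_dog_count_test(table, dogs, constrained_only=True,
                                exclude_dogs=("c3", "k3"))
    assert res["case_counts"].tolist() == [2, 1]
    assert res["control_counts"].tolist() == [1, 1]


def test_per_dog_exclude_coding_drops_missense():
    table, dogs = _burden_table()
    table = bd.classify_variants(table, dogs)
    res = bd.per_dog_count_test(table, dogs, constrained_only=True,
                                exclude_coding=True)
    assert res["case_counts"].tolist() == [1, 1, 0]


def test_planted_burden_gives_significant_per_dog_excess():
    # planted effect on the study scale (medians ~15 vs ~4)
    from breedmap.simulate import SimulationConfig, simulate_dataset
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        ds = simulate_dataset(SimulationConfig(seed=100 + seed))
        table = bd.classify_variants(ds.variant_table, ds.seq_dogs)
        res = bd.per_dog_count_test(table, ds.seq_dogs, constrained_only=True)
        hits += res["p"] < 0.05
    assert hits >= 0.9 * n_seeds


# ---------------------------------------------------------------------------
# gene burden
# ---------------------------------------------------------------------------

def _catalog():
    return pd.DataFrame([
        {"chrom": "chr1", "start": 0, "end": 5000, "name": "GA"},
        {"chrom": "chr1", "start": 100_000, "end": 110_000, "name": "GB"},
    ])


def test_gene_burden_counts_and_pseudocount_ratio():
    table, dogs = _burden_table()
    table = bd.classify_variants(table, dogs)
    res = bd.gene_burden(table, _catalog()).set_index("gene")
    # GA spans 0-5000 +5kb flank: variants at 1000-4000 inside
    assert res.loc["GA", "case_only"] == 2
    assert res.loc["GA", "control_only"] == 1
    assert res.loc["GA", "ratio"] == pytest.approx(3 / 2)
    assert res.loc["GB", "case_only"] == 0
    assert res.loc["GB", "ratio"] == pytest.approx(1.0)


def test_gene_burden_counts_monotone_in_flank():
    table, dogs = _burden_table()
    table = bd.classify_variants(table, dogs)
    b0 = bd.gene_burden(table, _catalog(), flank=0).set_index("gene")
    b5 = bd.gene_burden(table, _catalog(), flank=5000).set_index("gene")
    for g in ("GA", "GB"):
        assert b0.loc[g, "case_only"] <= b5.loc[g, "case_only"]
        assert b0.loc[g, "control_only"] <= b5.loc[g, "control_only"]


def test_planted_genes_rank_top4_and_counts_exact(dataset, default_config):
    table = bd.classify_variants(dataset.variant_table, dataset.seq_dogs)
    res = bd.gene_burden(table, dataset.catalog)
    planted = {g: (nc, nk) for g, nc, nk in default_config.planted_burden_genes}
    top = list(res["gene"].head(4))
    assert set(top) == set(planted)
    sub = res.set_index("gene")
    for g, (nc, nk) in planted.items():
        assert sub.loc[g, "case_only"] == nc
        assert sub.loc[g, "control_only"] == nk


def test_leave_breed_out_equals_manual_subsetting(dataset):
    table = dataset.variant_table
    dogs = dataset.seq_dogs
    breed = dogs["breed"].iloc[0]
    got = bd.leave_breed_out(table, dogs, breed, dataset.catalog)
    kept = dogs[dogs["breed"] != breed]
    dropped = dogs.loc[dogs["breed"] == breed, "sample"].tolist()
    manual = bd.gene_burden(
        bd.classify_variants(table.drop(columns=dropped), kept),
        dataset.catalog)
    pd.testing.assert_frame_equal(got, manual)


def test_leave_breed_out_emptying_a_group_raises():
    dogs = _dogs(case=("c1",), ctrl=("k1",), breeds=["b1", "b2"])
    table = pd.DataFrame([_variant(10, {"c1": 1, "k1": 0})])
    with pytest.raises(ValueError, match="empties"):
        bd.leave_breed_out(table, dogs, "b1", _catalog())


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def test_select_candidates_labels_all_six_criteria():
    dogs = _dogs(case=("c1", "c2", "c3"), ctrl=("k1", "k2", "k3"),
                 breeds=["dp", "dp", "jrt", "dp", "jrt", "jrt"])
    catalog = pd.DataFrame([
        {"chrom": "chr1", "start": 0, "end": 10_000, "name": "CDH2L"},
        {"chrom": "chr1", "start": 50_000, "end": 60_000, "name": "OTHER"},
    ])
    rows = [
        # (i) case-only, constrained, carried by a dp dog
        _variant(70_000, {"c1": 1, "c2": 0, "c3": 0, "k1": 0, "k2": 0, "k3": 0},
                 constrained=True),
        # (ii) case-only, constrained, inside focus gene CDH2L
        _variant(5_000, {"c1": 0, "c2": 0, "c3": 1, "k1": 0, "k2": 0, "k3": 0},
                 constrained=True),
        # (iii) case-only, constrained, carriers across two breeds (not dp? c2 dp c3 jrt)
        _variant(80_000, {"c1": 0, "c2": 1, "c3": 1, "k1": 0, "k2": 0, "k3": 0},
                 constrained=True),
        # (iv) nonsense case-only, NOT constrained
        _variant(90_000, {"c1": 0, "c2": 0, "c3": 1, "k1": 0, "k2": 0, "k3": 0},
                 consequence="nonsense"),
        # (v) inside risk haplotype, shared (selected regardless of status)
        _variant(120_500, {"c1": 1, "c2": 0, "c3": 0, "k1": 1, "k2": 0, "k3": 0}),
        # (vi) at a top GWAS position
        _variant(200_000, {"c1": 0, "c2": 1, "c3": 0, "k1": 1, "k2": 0, "k3": 0}),
        # unselected: case-only, unconstrained, noncoding, outside everything
        _variant(300_000, {"c1": 1, "c2": 0, "c3": 0, "k1": 0, "k2": 0, "k3": 0}),
    ]
    table = bd.classify_variants(pd.DataFrame(rows), dogs)
    assoc = pd.DataFrame({"id": ["a1", "a2"], "chrom": "chr1",
                          "pos": [200_000, 400_000], "chi2": [30.0, 1.0],
                          "p": [1e-6, 0.5]})
    out = bd.select_candidates(
        table, dogs, target_breed="dp", focus_genes=("CDH2L",),
        catalog=catalog, risk_haplotype=("chr1", 120_000, 121_000),
        assoc=assoc)
    labels = dict(zip(out["pos"], out["criteria"]))
    assert 300_000 not in labels
    assert "i" in labels[70_000]
    assert "ii" in labels[5_000]
    assert "iii" in labels[80_000]
    assert labels[90_000] == "iv"
    assert labels[120_500] == "v"
    assert labels[200_000] == "vi"
    assert len(out) == 6


def test_select_candidates_unknown_focus_gene_raises():
    dogs = _dogs()
    table = bd.classify_variants(pd.DataFrame(
        [_variant(10, {"c1": 1, "c2": 0, "k1": 0, "k2": 0})]), dogs)
    with pytest.raises(KeyError, match="NOPE"):
        bd.select_candidates(table, dogs, target_breed="b1",
                             focus_genes=("NOPE",), catalog=_catalog())


# ---------------------------------------------------------------------------
# genotyping QC and frequency contrast
# ---------------------------------------------------------------------------

def test_genotyping_qc_thresholds():
    rng = np.random.default_rng(0)
    n_dogs, n_var = 20, 40
    geno = rng.binomial(2, 0.3, size=(n_dogs, n_var)).astype(np.int8)
    geno[0, :5] = MISSING           # dog 0: 12.5% missing > 10% -> removed
    geno[1, :4] = MISSING           # dog 1: 10% exactly -> kept
    geno[3:, 10] = MISSING          # SNP10 call rate (after dog0 gone): low
    variants = pd.DataFrame({"id": [f"v{j}" for j in range(n_var)],
                             "chrom": "chr1", "pos": np.arange(n_var) * 100,
                             "ref": "A", "alt": "T"})
    samples = pd.DataFrame({"sample": [f"d{i}" for i in range(n_dogs)],
                            "breed": "x", "group": "unknown",
                            "breed_class": ["risk"] * 10 + ["control_breed"] * 10})
    panel = BreedPanel(geno, variants, samples)
    cleaned, report = bd.genotyping_qc(panel)
    removed_samples = set(report.loc[report["kind"] == "sample", "id"])
    assert removed_samples == {"d0"}
    removed_snps = set(report.loc[report["kind"] == "snp", "id"])
    assert "v10" in removed_snps
    assert cleaned.genotypes.shape[0] == 19


def test_normalized_af_diff_values():
    assert bd.normalized_af_diff(0.17, 0.05) == pytest.approx(
        0.12 / 0.22, abs=1e-12)
    assert bd.normalized_af_diff(0.2, 0.0) == 1.0
    assert bd.normalized_af_diff(0.3, 0.3) == 0.0
    assert np.isnan(bd.normalized_af_diff(0.0, 0.0))


def test_normalized_af_diff_rejects_out_of_range():
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        bd.normalized_af_diff(1.2, 0.5)


@settings(max_examples=200, deadline=None)
@given(st.floats(0, 1), st.floats(0, 1))
def test_normalized_af_diff_antisymmetric_and_bounded(a, b):
    f = bd.normalized_af_diff(a, b)
    g = bd.normalized_af_diff(b, a)
    if a + b == 0:
        assert np.isnan(f) and np.isnan(g)
    else:
        assert f == -g
        assert -1.0 <= f <= 1.0


def _hand_panel():
    """5 variants, 4 risk + 4 control dogs, no missingness."""
    g_risk = np.array([[1, 0, 2, 0, 1],
                       [0, 0, 1, 0, 1],
                       [1, 0, 1, 0, 0],
                       [0, 0, 2, 0, 0]], dtype=np.int8)
    g_ctrl = np.array([[0, 0, 1, 1, 0],
                       [0, 0, 0, 1, 0],
                       [1, 0, 1, 0, 0],
                       [0, 0, 0, 0, 0]], dtype=np.int8)
    geno = np.concatenate([g_risk, g_ctrl])
    variants = pd.DataFrame({"id": [f"v{j}" for j in range(5)],
                             "chrom": "chr1", "pos": np.arange(5) * 100,
                             "ref": "A", "alt": "T"})
    samples = pd.DataFrame({
        "sample": [f"d{i}" for i in range(8)], "breed": "x",
        "group": "unknown",
        "breed_class": ["risk"] * 4 + ["control_breed"] * 4})
    return BreedPanel(geno, variants, samples)


def test_frequency_contrast_matches_hand_computation():
    panel = _hand_panel()
    res = bd.frequency_contrast(panel)
    f_risk = np.array([2, 0, 6, 0, 2]) / 8.0
    f_ctrl = np.array([1, 0, 2, 2, 0]) / 8.0
    assert np.allclose(res["f_risk"], f_risk)
    assert np.allclose(res["f_ctrl"], f_ctrl)
    assert res["median_f_risk"] == pytest.approx(np.median(f_risk))
    assert res["median_f_ctrl"] == pytest.approx(np.median(f_ctrl))
    overall = (f_risk + f_ctrl) / 2.0
    norm = (f_risk - f_ctrl) / (f_risk + f_ctrl)
    norm[np.isnan(norm)] = np.nan
    from scipy import stats as ss
    ok = ~np.isnan(norm)
    r, _ = ss.pearsonr(overall[ok], norm[ok])
    assert res["pearson_r"] == pytest.approx(r)
    assert res["n_excluded_norm"] == 1          # variant 2 (all zero freq)


def test_frequency_contrast_identical_groups_is_null():
    g = np.tile(np.array([0, 1, 2, 0, 1], dtype=np.int8), (8, 1))
    variants = pd.DataFrame({"id": [f"v{j}" for j in range(5)],
                             "chrom": "chr1", "pos": np.arange(5) * 100,
                             "ref": "A", "alt": "T"})
    samples = pd.DataFrame({
        "sample": [f"d{i}" for i in range(8)], "breed": "x",
        "group": "unknown",
        "breed_class": ["risk"] * 4 + ["control_breed"] * 4})
    res = bd.frequency_contrast(BreedPanel(g, variants, samples))
    assert res["wilcoxon_p"] == 1.0
    assert np.nanmax(np.abs(res["normalized_diff"])) == 0.0


def test_frequency_contrast_planted_enrichment_gives_negative_r(dataset):
    panel, _ = bd.genotyping_qc(dataset.panel)
    res = bd.frequency_contrast(panel)
    assert res["pearson_r"] < -0.3
    assert res["median_f_risk"] > res["median_f_ctrl"]
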