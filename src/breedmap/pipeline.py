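"""End-to-end run: simulate -> call -> associate -> clump -> scan -> enrich
-> burden -> contrast, with every invariant validator applied.

The scans run on call-rate-filtered calls *without* the MAF filter: the
fixation criterion looks for near-monomorphic SNPs, which an association-
style MAF cut would delete. The MAF-filtered matrix feeds association only.
"""

from __future__ import annotations

import numpy as np

from . import assoc as am
from . import burden as bd
from . import caller as cl
from . import enrich as en
from . import scans as sc
from .simulate import CHROM, SimulationConfig, simulate_dataset


def run_pipeline(config: SimulationConfig | None = None,
                 n_perm: int = 2_000) -> dict:
    """Run the whole mapping workflow on a synthetic study.

    Returns a dict of stage outputs and headline numbers; raises if any
    internal validator fails.
    """
    config = config or SimulationConfig()
    ds = simulate_dataset(config)
    out: dict = {"dataset": ds}

    # genotype calling + concordance against planted truth
    callset = cl.call_genotypes(ds.intensities)
    calls = callset.to_genotype_matrix()
    out["concordance"] = cl.concordance(calls, ds.truth_genotypes)

    # cohort QC: call-rate-only matrix for scans, full QC for association
    scan_gm, _ = cl.qc_filter(calls, apply_maf=False)
    assoc_gm, qc_report = cl.qc_filter(calls)
    out["qc_report"] = qc_report

    # association and clumping
    assoc_res = am.allelic_chisq(assoc_gm)
    regions = am.clump(assoc_res, assoc_gm)
    am.validate_clumps(regions, assoc_res)
    region_genes = am.expand_regions(regions, ds.catalog)
    out["assoc"] = assoc_res
    out["regions"] = regions
    out["region_genes"] = region_genes
    top_pos = None
    if len(regions):
        best = regions.regions.sort_values("score").iloc[0]
        top_pos = (int(best["start"]), int(best["end"]))
    out["top_region"] = top_pos

    # selection scans on the target breed
    target = config.breeds[0]
    target_gm = scan_gm.by_breed(target)
    fixed = sc.fixation_scan(target_gm)
    sc.validate_fixation_regions(fixed, target_gm)
    refs = [scan_gm.by_breed(b) for b in config.breeds[1:]]
    rrv, rrv_windows = sc.rrv_scan(target_gm, refs)
    out["fixed_regions"] = fixed
    out["rrv_regions"] = rrv
    out["rrv_windows"] = rrv_windows

    # permutation gene-set enrichment of the association regions
    chrom_lengths = {CHROM: config.chrom_length}
    if len(regions):
        sets, _ = en.filter_sets(ds.sets, ds.catalog)
        enr = en.permutation_enrichment(
            regions, sets, ds.catalog, chrom_lengths,
            n_perm=n_perm, seed=config.seed, flank=am.EXPAND_FLANK)
        assert (enr["empirical_p"] > 0).all()
        assert (enr["corrected_p"] >= enr["empirical_p"] - 1e-12).all()
        out["enrichment"] = enr

    # case-only burden on the sequencing panel
    table = bd.classify_variants(ds.variant_table, ds.seq_dogs)
    counts = table["status"].value_counts()
    assert int(counts.sum()) == len(table)
    per_dog = bd.per_dog_count_test(table, ds.seq_dogs, constrained_only=True)
    burden = bd.gene_burden(table, ds.catalog)
    out["variant_table"] = table
    out["per_dog"] = per_dog
    out["burden"] = burden
    planted = [g for g, _, _ in config.planted_burden_genes]
    out["planted_top4"] = set(burden["gene"].head(len(planted))) == set(planted)

    # breed-panel QC and frequency contrast
    panel, panel_report = bd.genotyping_qc(ds.panel)
    out["panel_report"] = panel_report
    out["contrast"] = bd.frequency_contrast(panel)
    out["panel_shape"] = (panel.genotypes.shape[0], panel.genotypes.shape[1])

    # compact summary of headline numbers
    out["summary"] = {
        "caller_concordance": out["concordance"]["concordance"],
        "n_regions": len(regions),
        "n_fixed_regions": len(fixed),
        "n_rrv_windows": int(rrv_windows["selected"].sum()),
        "per_dog_median_case": per_dog["median_case"],
        "per_dog_median_control": per_dog["median_control"],
        "per_dog_p": per_dog["p"],
        "median_f_risk": out["contrast"]["median_f_risk"],
        "median_f_ctrl": out["contrast"]["median_f_ctrl"],
        "pearson_r": out["contrast"]["pearson_r"],
    }
    return out


def planted_locus_in_top_region(out: dict, config: SimulationConfig) -> bool:
    """Whether the best clump covers the planted associated position."""
    if out["top_region"] is None:
        return False
    pos = config.planted_assoc[0][0]
    lo, hi = out["top_region"]
    return lo <= pos < hi


def planted_fixed_region_recovered(out: dict, config: SimulationConfig) -> bool:
    fs, fe, _ = config.planted_fixed_region
    for _, row in out["fixed_regions"].regions.iterrows():
        if row["start"] <= fs and row["end"] >= fe - 1:
            return True
    return False


def decoy_region_reported(out: dict, config: SimulationConfig) -> bool:
    ds_, de, _ = config.planted_decoy_region
    mid = (ds_ + de) // 2
    for _, row in out["fixed_regions"].regions.iterrows():
        if row["start"] <= mid < row["end"]:
            return True
    return False


def planted_rrv_recovered(out: dict, config: SimulationConfig) -> bool:
    rs, re_, _ = config.planted_rrv_region
    tab = out["rrv_windows"]
    sel = tab[tab["selected"]]
    hit = (sel["start"] <= rs) & (sel["end"] >= re_)
    return bool(hit.any())


def planted_burden_counts(out: dict, config: SimulationConfig) -> dict:
    """Recovered (case-only, control-only) counts for each planted gene."""
    burden = out["burden"].set_index("gene")
    res = {}
    for gene, n_case, n_ctrl in config.planted_burden_genes:
        row = burden.loc[gene]
        res[gene] = (int(row["case_only"]), int(row["control_only"]),
                     n_case, n_ctrl)
    return res
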