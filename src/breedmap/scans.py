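"""Breed fixation regions and regions of reduced variability (RRV).

A fixation region is a maximal run of consecutive SNPs spanning more than
1 Mb, containing more than five SNPs, with more than 95% of them at
MAF < 0.05 in the scanned breed. RRVs tile the genome in 150 kb windows,
score each window by mean expected heterozygosity 2p(1-p), normalize the
target breed's score by the mean over reference breeds, and report the
lowest 1% of windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, RegionSet

FIX_MIN_SPAN = 1_000_000
FIX_MIN_SNPS = 6          # "more than five SNPs"
FIX_MAF = 0.05
FIX_FRAC = 0.95           # strictly more than 95% of SNPs below FIX_MAF
RRV_WINDOW = 150_000
RRV_QUANTILE = 0.01
RRV_EPS = 1e-6


def _qualifies(pos, low, i, j, min_span, min_snps, frac):
    count = j - i + 1
    if count < min_snps:
        return False
    if pos[j] - pos[i] <= min_span:
        return False
    return (low[i:j + 1].sum() / count) > frac


def fixation_scan(gm: GenotypeMatrix, min_span: int = FIX_MIN_SPAN,
                  min_snps: int = FIX_MIN_SNPS, maf_thresh: float = FIX_MAF,
                  frac: float = FIX_FRAC) -> RegionSet:
    """All maximal fixation intervals of one breed's genotypes.

    An interval of consecutive SNPs qualifies when its genomic span exceeds
    ``min_span`` bp, it holds at least ``min_snps`` SNPs, and the fraction
    at MAF < ``maf_thresh`` strictly exceeds ``frac``. Maximality means
    neither adjacent SNP can be absorbed without violating a criterion.
    SNP order is internal (sorted by position), so input order is irrelevant.
    Maximal intervals can overlap; every reported interval individually
    satisfies all three criteria.
    """
    order = np.lexsort((gm.snps["pos"].to_numpy(),
                        gm.snps["chrom"].astype(str).to_numpy()))
    snps = gm.snps.iloc[order].reset_index(drop=True)
    maf = gm.subset(snp_idx=order).maf()
    regions = []
    for chrom, sub in snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        low = (np.nan_to_num(maf[idx], nan=0.0) < maf_thresh).astype(int)
        n = len(pos)
        cum = np.concatenate([[0], np.cumsum(low)])
        found = []
        for i in range(n):
            counts = np.arange(1, n - i + 1)
            spans = pos[i:] - pos[i]
            fracs = (cum[i + 1:] - cum[i]) / counts
            ok = (counts >= min_snps) & (spans > min_span) & (fracs > frac)
            for j0 in np.flatnonzero(ok):
                found.append((i, i + j0))
        maximal = []
        qual = set(found)
        for i, j in found:
            if (i - 1, j) in qual or (i, j + 1) in qual:
                continue
            if i > 0 and _qualifies(pos, low, i - 1, j, min_span, min_snps, frac):
                continue
            if j < n - 1 and _qualifies(pos, low, i, j + 1, min_span, min_snps, frac):
                continue
            maximal.append((int(pos[i]), int(pos[j]) + 1))
        # maximal intervals may overlap (extending one violates a criterion
        # the other still meets); all are reported, each criterion-true
        maximal.sort()
        for s, e in maximal:
            regions.append({"chrom": chrom, "start": s, "end": e,
                            "label": f"fix{len(regions) + 1}",
                            "score": float(e - s)})
    return RegionSet(pd.DataFrame(
        regions, columns=["chrom", "start", "end", "label", "score"]))


def validate_fixation_regions(regions: RegionSet, gm: GenotypeMatrix,
                              min_span: int = FIX_MIN_SPAN,
                              min_snps: int = FIX_MIN_SNPS,
                              maf_thresh: float = FIX_MAF,
                              frac: float = FIX_FRAC) -> None:
    """Re-check every reported region against the three printed criteria."""
    order = np.argsort(gm.snps["pos"].to_numpy())
    pos = gm.snps["pos"].to_numpy()[order]
    chroms = gm.snps["chrom"].to_numpy()[order]
    maf = np.nan_to_num(gm.subset(snp_idx=order).maf(), nan=0.0)
    for _, row in regions.regions.iterrows():
        inside = (chroms == row["chrom"]) & (pos >= row["start"]) & (pos < row["end"])
        count = int(inside.sum())
        assert count >= min_snps, "fixation region holds too few SNPs"
        span = pos[inside].max() - pos[inside].min()
        assert span > min_span, "fixation region span below threshold"
        lowfrac = (maf[inside] < maf_thresh).mean()
        assert lowfrac > frac, "fixation region MAF fraction below threshold"


# ---------------------------------------------------------------------------
# RRV scan
# ---------------------------------------------------------------------------

def window_heterozygosity(gm: GenotypeMatrix, window: int = RRV_WINDOW) -> pd.DataFrame:
    """Mean expected heterozygosity 2p(1-p) per non-overlapping window."""
    p = gm.allele_freq()
    het = 2.0 * p * (1.0 - p)
    df = pd.DataFrame({
        "chrom": gm.snps["chrom"],
        "win": gm.snps["pos"].to_numpy() // window,
        "het": het,
    }).dropna(subset=["het"])
    agg = df.groupby(["chrom", "win"], sort=True)["het"].agg(["mean", "size"])
    agg = agg.reset_index().rename(columns={"mean": "het", "size": "n_snps"})
    agg["start"] = agg["win"] * window
    agg["end"] = (agg["win"] + 1) * window
    return agg


def rrv_scan(target: GenotypeMatrix, references: list[GenotypeMatrix],
             window: int = RRV_WINDOW, quantile: float = RRV_QUANTILE,
             eps: float = RRV_EPS, mode: str = "relative",
             merge_adjacent: bool = True):
    """Regions of reduced variability of the target breed.

    Windows with at least one scored SNP in the target and in at least one
    reference are retained; the rest are dropped and logged in the returned
    window table. The relative score is target het / (mean reference het +
    eps); ``mode='absolute'`` ranks on the target het alone. Exactly
    floor(quantile x retained windows) windows are selected (ties broken by
    window order); adjacent selected windows are merged in the RegionSet.

    Returns (RegionSet, window table with ``selected`` flags).
    """
    if not references:
        raise ValueError("need at least one reference breed")
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    t = window_heterozygosity(target, window).set_index(["chrom", "win"])
    refs = [window_heterozygosity(r, window).set_index(["chrom", "win"])
            for r in references]
    ref_mean = pd.concat([r["het"] for r in refs], axis=1).mean(axis=1)
    tab = t.copy()
    tab["ref_het"] = ref_mean
    tab = tab.dropna(subset=["ref_het"])
    if mode == "relative":
        tab["score"] = tab["het"] / (tab["ref_het"] + eps)
    else:
        tab["score"] = tab["het"]
    tab = tab.reset_index()
    n_keep = int(np.floor(quantile * len(tab)))
    order = np.lexsort((tab["win"].to_numpy(), tab["chrom"].astype(str).to_numpy(),
                        tab["score"].to_numpy()))
    selected = np.zeros(len(tab), dtype=bool)
    selected[order[:n_keep]] = True
    tab["selected"] = selected
    sel = tab[selected].sort_values(["chrom", "start"])
    regions = []
    for _, row in sel.iterrows():
        if (merge_adjacent and regions and regions[-1]["chrom"] == row["chrom"]
                and regions[-1]["end"] == row["start"]):
            regions[-1]["end"] = int(row["end"])
        else:
            regions.append({"chrom": row["chrom"], "start": int(row["start"]),
                            "end": int(row["end"]),
                            "label": f"rrv{len(regions) + 1}",
                            "score": float(row["score"])})
    rs = RegionSet(pd.DataFrame(
        regions, columns=["chrom", "start", "end", "label", "score"]))
    return rs, tab


# ---------------------------------------------------------------------------
# cross-breed differential gene-set scoring
# ---------------------------------------------------------------------------

def differential_set_enrichment(target_p: dict, reference_p: dict,
                                rrv_gene_counts: dict,
                                p_thresh: float = 0.05,
                                min_genes: int = 2) -> pd.DataFrame:
    """Score gene sets enriched in the target breed but not the references.

    Candidate sets have target enrichment P < ``p_thresh`` and at least
    ``min_genes`` RRV genes in the target. The score is the mean over
    reference breeds of (reference P - target P); breeds missing a set's P
    are dropped from that mean and logged. Sets whose target P undercuts
    every reference P are flagged as breed-specific.
    """
    rows = []
    for name, pt in target_p.items():
        if pt >= p_thresh or rrv_gene_counts.get(name, 0) < min_genes:
            continue
        ref_ps, missing = [], []
        for breed, pmap in reference_p.items():
            if name in pmap and not pd.isna(pmap[name]):
                ref_ps.append(pmap[name])
            else:
                missing.append(breed)
        if not ref_ps:
            continue
        rows.append({
            "set": name,
            "target_p": pt,
            "score": float(np.mean([p - pt for p in ref_ps])),
            "breed_specific": bool(pt < min(ref_ps)),
            "n_ref": len(ref_ps),
            "missing_refs": ",".join(missing),
        })
    df = pd.DataFrame(rows, columns=["set", "target_p", "score",
                                     "breed_specific", "n_ref", "missing_refs"])
    return df.sort_values("score", ascending=False).reset_index(drop=True)
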