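"""Case/control allelic association, LD and clumping into candidate regions.

Association uses the standard 1-df allelic chi-squared on 2x2 allele-count
tables (no continuity correction, missing genotypes dropped per SNP). LD is
the squared Pearson correlation of genotype dosages over pairwise-complete
samples. Clumping greedily picks the most significant unassigned SNP with
P below the index threshold and absorbs unassigned SNPs within 1 Mb with
r^2 above 0.8 and P below the member threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .containers import MISSING, GenotypeMatrix, RegionSet

P_INDEX = 1e-4
P_MEMBER = 0.01
CLUMP_WINDOW = 1_000_000
CLUMP_R2 = 0.8
EXPAND_FLANK = 500_000


def allelic_chisq(gm: GenotypeMatrix, phenotype=None) -> pd.DataFrame:
    """Allelic chi-squared per SNP.

    ``phenotype`` is a boolean case indicator per sample; defaults to
    ``gm.samples['group'] == 'case'``. Monomorphic SNPs get statistic 0,
    P = 1 and a flag. Returns a DataFrame with one row per SNP:
    id, chrom, pos, chi2, p, maf, and the four allele counts.
    """
    if phenotype is None:
        phenotype = (gm.samples["group"] == "case").to_numpy()
    phenotype = np.asarray(phenotype, dtype=bool)
    if phenotype.sum() == 0 or (~phenotype).sum() == 0:
        raise ValueError("need at least one case and one control")
    g = gm.genotypes
    called = g != MISSING
    gz = np.where(called, g, 0)

    def group_counts(mask):
        alt = (gz[mask] * called[mask]).sum(axis=0)
        n_called = called[mask].sum(axis=0)
        return alt.astype(float), (2 * n_called - alt).astype(float)

    a, b = group_counts(phenotype)       # case alt / case ref
    c, d = group_counts(~phenotype)      # control alt / control ref
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    alt_freq = np.where(n > 0, (a + c) / n, np.nan)
    mono = (a + c == 0) | (b + d == 0) | (n == 0)
    stat = np.where(mono, 0.0, stat)
    p = chi2_dist.sf(stat, df=1)
    p = np.where(mono, 1.0, p)
    return pd.DataFrame({
        "id": gm.snps["id"], "chrom": gm.snps["chrom"], "pos": gm.snps["pos"],
        "chi2": stat, "p": p,
        "maf": np.minimum(alt_freq, 1 - alt_freq),
        "case_alt": a, "case_ref": b, "ctrl_alt": c, "ctrl_ref": d,
        "flag_monomorphic": mono,
    })


def chisq_from_counts(a: float, b: float, c: float, d: float):
    """Closed-form 1-df chi-squared for an allele-count table.

    ``a``/``b`` are case risk/other allele counts, ``c``/``d`` the control
    counts. Returns (statistic, p).
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return float(stat), float(chi2_dist.sf(stat, df=1))


def ld_r2(x: np.ndarray, y: np.ndarray):
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples; returns (r2, flagged) where the
    flag marks an undefined value (fewer than 3 complete pairs or a
    degenerate vector), reported as r2 = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 3:
        return 0.0, True
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0, True
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r * r, False


def ld_r2_matrix(g: np.ndarray, index: int, candidates: np.ndarray) -> np.ndarray:
    """r^2 of one index SNP against candidate columns, vectorized."""
    out = np.zeros(len(candidates))
    for k, j in enumerate(candidates):
        out[k], _ = ld_r2(g[:, index], g[:, j])
    return out


def clump(assoc: pd.DataFrame, gm: GenotypeMatrix, p_index: float = P_INDEX,
          p_member: float = P_MEMBER, window: int = CLUMP_WINDOW,
          r2_min: float = CLUMP_R2) -> RegionSet:
    """Greedy LD clumping of association results into candidate regions.

    Repeatedly takes the unassigned SNP with the smallest P among those with
    P < ``p_index`` (ties broken by smaller position) as the index, then
    assigns every unassigned SNP within ``window`` bp (index-to-SNP,
    inclusive) with r^2 > ``r2_min`` and P < ``p_member`` to its clump. The
    region spans the min..max member positions (half-open). No qualifying
    index SNP yields an empty RegionSet.
    """
    order = np.lexsort((assoc["pos"].to_numpy(), assoc["p"].to_numpy()))
    pos = assoc["pos"].to_numpy()
    chrom = assoc["chrom"].to_numpy()
    pvals = assoc["p"].to_numpy()
    assigned = np.zeros(len(assoc), dtype=bool)
    regions, members = [], {}
    n_clump = 0
    for idx in order:
        if assigned[idx] or pvals[idx] >= p_index:
            continue
        n_clump += 1
        label = f"clump{n_clump}"
        near = np.flatnonzero(
            (~assigned) & (chrom == chrom[idx])
            & (np.abs(pos - pos[idx]) <= window) & (pvals < p_member))
        near = near[near != idx]
        r2 = ld_r2_matrix(gm.genotypes, idx, near)
        member_idx = [idx] + [int(j) for j, r in zip(near, r2) if r > r2_min]
        assigned[member_idx] = True
        mpos = pos[member_idx]
        regions.append({"chrom": chrom[idx], "start": int(mpos.min()),
                        "end": int(mpos.max()) + 1, "label": label,
                        "score": float(pvals[idx])})
        members[label] = assoc["id"].to_numpy()[member_idx].tolist()
    return RegionSet(pd.DataFrame(regions,
                                  columns=["chrom", "start", "end", "label", "score"]),
                     members)


def validate_clumps(regions: RegionSet, assoc: pd.DataFrame,
                    p_index: float = P_INDEX, p_member: float = P_MEMBER,
                    window: int = CLUMP_WINDOW) -> None:
    """Independent post-hoc check of the printed clumping criteria."""
    by_id = assoc.set_index("id")
    seen: set[str] = set()
    for label, ids in regions.members.items():
        row = regions.regions.set_index("label").loc[label]
        index_p = row["score"]
        index_pos = None
        for sid in ids:
            if by_id.loc[sid, "p"] == index_p:
                index_pos = by_id.loc[sid, "pos"]
                break
        assert index_p < p_index, "index SNP fails the index P threshold"
        for sid in ids:
            assert sid not in seen, f"SNP {sid} assigned to two clumps"
            seen.add(sid)
            assert by_id.loc[sid, "p"] < p_member or by_id.loc[sid, "p"] == index_p
            if index_pos is not None:
                assert abs(by_id.loc[sid, "pos"] - index_pos) <= window


def expand_regions(regions: RegionSet, catalog: pd.DataFrame,
                   flank: int = EXPAND_FLANK) -> dict[str, list[str]]:
    """Map each region to the genes overlapping region +/- ``flank``.

    Gene intervals are half-open; a gene overlaps the flanked region iff
    gene.start < end + flank and gene.end > max(start - flank, 0).
    """
    out: dict[str, list[str]] = {}
    for _, row in regions.regions.iterrows():
        lo = max(int(row["start"]) - flank, 0)
        hi = int(row["end"]) + flank
        sub = catalog[(catalog["chrom"] == row["chrom"])
                      & (catalog["start"] < hi) & (catalog["end"] > lo)]
        out[row["label"]] = sub["name"].tolist()
    return out
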