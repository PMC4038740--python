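"""Case-only variant classification, burden analysis and breed contrasts.

Variants carried by at least one affected dog and absent from every
unaffected dog are "case-only" (and symmetrically "control-only"); because
absence is only meaningful where genotypes were actually called, exclusive
status additionally requires a minimum call rate in the opposite group
(default: every opposite-group dog called). Burden per gene counts exclusive
variants within the gene span plus a 5 kb flank on each side, overall and
restricted to evolutionarily constrained elements, and ranks genes by the
pseudocounted case/control ratio within constrained elements. Breed-panel
frequency contrasts use the normalized allele-frequency difference
(a - b)/(a + b).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .containers import MISSING, BreedPanel, variant_dog_columns

GENE_FLANK = 5_000
CODING_CONSEQUENCES = {"missense", "nonsense", "frameshift", "silent", "splice"}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_variants(table: pd.DataFrame, dogs: pd.DataFrame,
                      control_callrate_min: float = 1.0) -> pd.DataFrame:
    """Assign case-only / control-only / shared / private-missing status.

    A variant is case-only when its alternate allele is carried by >= 1 case,
    by 0 controls, and the genotype is non-missing in at least
    ``control_callrate_min`` of the controls (symmetric for control-only).
    Exclusive variants failing the opposite-group call-rate requirement are
    "private-missing"; everything else (carriers in both groups, or no
    carriers at all) is "shared". Variants missing in every dog are dropped.

    Returns a copy of the table with ``status`` plus per-group carrier and
    call-rate columns.
    """
    if not len(dogs):
        raise ValueError("empty sample sheet")
    case_dogs = dogs.loc[dogs["group"] == "case", "sample"].tolist()
    ctrl_dogs = dogs.loc[dogs["group"] == "control", "sample"].tolist()
    if not case_dogs or not ctrl_dogs:
        raise ValueError("need at least one case and one control dog")
    g_case = table[case_dogs].to_numpy(dtype=float)
    g_ctrl = table[ctrl_dogs].to_numpy(dtype=float)
    case_called = (g_case != MISSING)
    ctrl_called = (g_ctrl != MISSING)
    case_carriers = ((g_case >= 1) & case_called).sum(axis=1)
    ctrl_carriers = ((g_ctrl >= 1) & ctrl_called).sum(axis=1)
    case_rate = case_called.mean(axis=1)
    ctrl_rate = ctrl_called.mean(axis=1)

    out = table.copy()
    out["case_carriers"] = case_carriers
    out["ctrl_carriers"] = ctrl_carriers
    out["case_call_rate"] = case_rate
    out["ctrl_call_rate"] = ctrl_rate
    status = np.full(len(out), "shared", dtype=object)
    case_only = (case_carriers >= 1) & (ctrl_carriers == 0)
    ctrl_only = (ctrl_carriers >= 1) & (case_carriers == 0)
    status[case_only & (ctrl_rate >= control_callrate_min)] = "case-only"
    status[case_only & (ctrl_rate < control_callrate_min)] = "private-missing"
    status[ctrl_only & (case_rate >= control_callrate_min)] = "control-only"
    status[ctrl_only & (case_rate < control_callrate_min)] = "private-missing"
    out["status"] = status
    all_missing = (case_rate == 0) & (ctrl_rate == 0)
    return out[~all_missing].reset_index(drop=True)


def intersect_constrained(table: pd.DataFrame,
                          constrained: pd.DataFrame) -> pd.DataFrame:
    """Flag variants inside constrained elements (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    for _, row in constrained.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if start >= end:
            continue
        trees.setdefault(row["chrom"], IntervalTree()).addi(start, end)
    out = table.copy()
    out["constrained"] = [
        bool(trees.get(c) and trees[c].overlaps_point(int(p)))
        for c, p in zip(out["chrom"], out["pos"])
    ]
    return out


# ---------------------------------------------------------------------------
# per-dog counts and rank-sum test
# ---------------------------------------------------------------------------

def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; exact when both groups have <= 10 values.

    Returns (statistic, p). Above 10 per group the normal approximation with
    tie correction is used. Identical samples give P = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("rank-sum test needs at least 2 values per group")
    method = "exact" if max(len(x), len(y)) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def per_dog_count_test(table: pd.DataFrame, dogs: pd.DataFrame,
                       constrained_only: bool = False,
                       exclude_coding: bool = False,
                       exclude_dogs: tuple = ()) -> dict:
    """Per-dog exclusive-variant counts and their case/control comparison.

    For each case dog, counts the case-only variants it carries; for each
    control dog, the control-only variants. ``constrained_only`` restricts to
    constrained elements, ``exclude_coding`` drops coding consequences, and
    ``exclude_dogs`` removes named dogs (e.g. a pair with poor genotyping
    accuracy) before testing. The comparison is a two-sided Wilcoxon
    rank-sum, exact at these group sizes.
    """
    dogs = dogs[~dogs["sample"].isin(exclude_dogs)]
    sub = table
    if constrained_only:
        sub = sub[sub["constrained"].astype(bool)]
    if exclude_coding:
        sub = sub[~sub["consequence"].isin(CODING_CONSEQUENCES)]
    counts = {}
    for group, status in (("case", "case-only"), ("control", "control-only")):
        names = dogs.loc[dogs["group"] == group, "sample"].tolist()
        if len(names) < 2:
            raise ValueError(f"fewer than 2 {group} dogs after exclusions")
        rows = sub[sub["status"] == status]
        g = rows[names].to_numpy(dtype=float)
        counts[group] = pd.Series(((g >= 1) & (g != MISSING)).sum(axis=0),
                                  index=names)
    stat, p = rank_sum_test(counts["case"].to_numpy(),
                            counts["control"].to_numpy())
    return {
        "case_counts": counts["case"], "control_counts": counts["control"],
        "median_case": float(counts["case"].median()),
        "median_control": float(counts["control"].median()),
        "statistic": stat, "p": p,
    }


# ---------------------------------------------------------------------------
# gene burden
# ---------------------------------------------------------------------------

def gene_burden(table: pd.DataFrame, catalog: pd.DataFrame,
                flank: int = GENE_FLANK) -> pd.DataFrame:
    """Case-only / control-only counts per gene (span +/- flank).

    Reports raw counts overall and restricted to constrained elements, plus
    the pseudocounted ratio (case + 1)/(control + 1) for each; genes are
    ranked by constrained ratio, then constrained case-only count. The raw
    counts allow recovering the unpseudocounted ratio.
    """
    pos = table["pos"].to_numpy()
    chrom = table["chrom"].to_numpy()
    is_case = (table["status"] == "case-only").to_numpy()
    is_ctrl = (table["status"] == "control-only").to_numpy()
    cons = table["constrained"].to_numpy(dtype=bool)
    rows = []
    for _, g in catalog.iterrows():
        lo, hi = int(g["start"]) - flank, int(g["end"]) + flank
        inside = (chrom == g["chrom"]) & (pos >= lo) & (pos < hi)
        n_case = int((inside & is_case).sum())
        n_ctrl = int((inside & is_ctrl).sum())
        n_case_c = int((inside & is_case & cons).sum())
        n_ctrl_c = int((inside & is_ctrl & cons).sum())
        rows.append({
            "gene": g["name"], "chrom": g["chrom"],
            "start": int(g["start"]), "end": int(g["end"]),
            "case_only": n_case, "control_only": n_ctrl,
            "ratio": (n_case + 1) / (n_ctrl + 1),
            "case_only_constrained": n_case_c,
            "control_only_constrained": n_ctrl_c,
            "ratio_constrained": (n_case_c + 1) / (n_ctrl_c + 1),
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(["ratio_constrained", "case_only_constrained", "gene"],
                        ascending=[False, False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def leave_breed_out(table: pd.DataFrame, dogs: pd.DataFrame, breed: str,
                    catalog: pd.DataFrame, flank: int = GENE_FLANK,
                    control_callrate_min: float = 1.0) -> pd.DataFrame:
    """Reclassify and recompute burden with one breed's dogs removed."""
    kept = dogs[dogs["breed"] != breed]
    if (kept["group"] == "case").sum() == 0 or (kept["group"] == "control").sum() == 0:
        raise ValueError(f"removing breed {breed!r} empties a phenotype group")
    dropped = dogs.loc[dogs["breed"] == breed, "sample"].tolist()
    sub = table.drop(columns=[d for d in dropped if d in table.columns])
    sub = classify_variants(sub, kept, control_callrate_min=control_callrate_min)
    return gene_burden(sub, catalog, flank=flank)


# ---------------------------------------------------------------------------
# genotyping candidate selection
# ---------------------------------------------------------------------------

def _carrier_breeds(table: pd.DataFrame, dogs: pd.DataFrame) -> list[set]:
    by_dog = dict(zip(dogs["sample"], dogs["breed"]))
    dog_cols = [c for c in variant_dog_columns(table) if c in by_dog]
    g = table[dog_cols].to_numpy(dtype=float)
    out = []
    for row in (g >= 1) & (g != MISSING):
        out.append({by_dog[dog_cols[k]] for k in np.flatnonzero(row)})
    return out


def select_candidates(table: pd.DataFrame, dogs: pd.DataFrame,
                      target_breed: str, focus_genes: tuple,
                      catalog: pd.DataFrame,
                      risk_haplotype: tuple | None = None,
                      assoc: pd.DataFrame | None = None,
                      assoc_p_max: float = 1e-4,
                      criteria: tuple = ("i", "ii", "iii", "iv", "v", "vi")
                      ) -> pd.DataFrame:
    """Select variants for follow-up genotyping by the six design criteria.

    (i) case-only in the target breed; (ii) case-only in the focus genes;
    (iii) case-only in >= 2 breeds; (iv) potential functional variants
    (nonsense / splice / damaging missense annotation) case-only in >= 1
    breed; (v) inside the risk haplotype interval (chrom, start, end);
    (vi) top GWAS-associated positions (P < ``assoc_p_max``). Criteria
    i-iii are restricted to constrained elements. Each selected variant is
    labeled with every criterion it meets.
    """
    known = set(catalog["name"])
    unknown = [g for g in focus_genes if g not in known]
    if unknown:
        raise KeyError(f"focus genes not in catalog: {unknown}")
    breeds = _carrier_breeds(table, dogs)
    cons = table["constrained"].to_numpy(dtype=bool)
    case_only = (table["status"] == "case-only").to_numpy()
    labels: list[list[str]] = [[] for _ in range(len(table))]

    focus_spans = catalog[catalog["name"].isin(focus_genes)]

    for i in range(len(table)):
        row = table.iloc[i]
        if case_only[i] and cons[i]:
            if "i" in criteria and target_breed in breeds[i]:
                labels[i].append("i")
            if "ii" in criteria:
                for _, g in focus_spans.iterrows():
                    if (row["chrom"] == g["chrom"]
                            and g["start"] - GENE_FLANK <= row["pos"]
                            < g["end"] + GENE_FLANK):
                        labels[i].append("ii")
                        break
            if "iii" in criteria and len(breeds[i]) >= 2:
                labels[i].append("iii")
        if ("iv" in criteria and case_only[i]
                and row["consequence"] in ("nonsense", "splice", "missense",
                                           "frameshift")):
            labels[i].append("iv")
        if "v" in criteria and risk_haplotype is not None:
            hc, hs, he = risk_haplotype
            if row["chrom"] == hc and hs <= row["pos"] < he:
                labels[i].append("v")
    if "vi" in criteria and assoc is not None:
        top = assoc[assoc["p"] < assoc_p_max]
        top_pos = set(zip(top["chrom"], top["pos"]))
        for i in range(len(table)):
            row = table.iloc[i]
            if (row["chrom"], row["pos"]) in top_pos:
                labels[i].append("vi")
    sel = [i for i, lab in enumerate(labels) if lab]
    out = table.iloc[sel].copy()
    out["criteria"] = [",".join(labels[i]) for i in sel]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# breed-panel QC and frequency contrast
# ---------------------------------------------------------------------------

def genotyping_qc(panel: BreedPanel, sample_missing_max: float = 0.10,
                  snp_callrate_min: float = 0.90):
    """Panel QC: drop samples with missingness > 10%, then SNPs with call
    rate < 90%. Returns (cleaned panel, removal report)."""
    if panel.genotypes.size == 0:
        raise ValueError("empty panel")
    report = []
    called = panel.genotypes != MISSING
    sample_missing = 1.0 - called.mean(axis=1)
    keep_s = sample_missing <= sample_missing_max
    for i in np.flatnonzero(~keep_s):
        report.append({"kind": "sample", "id": panel.samples["sample"].iat[i],
                       "reason": "missingness", "value": float(sample_missing[i])})
    geno = panel.genotypes[keep_s]
    samples = panel.samples[keep_s].reset_index(drop=True)
    rate = (geno != MISSING).mean(axis=0)
    keep_v = rate >= snp_callrate_min
    for j in np.flatnonzero(~keep_v):
        report.append({"kind": "snp", "id": panel.variants["id"].iat[j],
                       "reason": "call_rate", "value": float(rate[j])})
    if not keep_s.any() or not keep_v.any():
        raise ValueError("genotyping QC removed everything")
    cleaned = BreedPanel(geno[:, keep_v], panel.variants[keep_v], samples)
    return cleaned, pd.DataFrame(report, columns=["kind", "id", "reason", "value"])


def normalized_af_diff(af_risk, af_ctrl):
    """Normalized allele-frequency difference (a - b)/(a + b) in [-1, 1].

    Accepts scalars or arrays; frequencies must lie in [0, 1]. Where both
    frequencies are zero the statistic is undefined and NaN is returned.
    """
    a = np.asarray(af_risk, dtype=float)
    b = np.asarray(af_ctrl, dtype=float)
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(a + b > 0, (a - b) / np.where(a + b > 0, a + b, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def frequency_contrast(panel: BreedPanel, min_variants: int = 5) -> dict:
    """Risk-vs-control breed frequency contrast of the panel variants.

    Reports per-group median frequencies, a two-sided Wilcoxon signed-rank
    test on the per-variant paired frequencies, and the Pearson correlation
    between the overall allele frequency and the normalized frequency
    difference. Variants with undefined statistics are excluded and flagged.
    """
    f_risk = panel.group_freq("risk")
    f_ctrl = panel.group_freq("control_breed")
    ok = ~(np.isnan(f_risk) | np.isnan(f_ctrl))
    f_risk, f_ctrl = f_risk[ok], f_ctrl[ok]
    if len(f_risk) < min_variants:
        raise ValueError(f"fewer than {min_variants} variants survive QC")
    diffs = f_risk - f_ctrl
    if np.allclose(diffs, 0.0):
        wstat, wp = 0.0, 1.0
    else:
        res = stats.wilcoxon(f_risk, f_ctrl, zero_method="zsplit",
                             alternative="two-sided")
        wstat, wp = float(res.statistic), float(res.pvalue)

    g = np.ma.masked_equal(panel.genotypes[:, ok], MISSING)
    overall = (g.mean(axis=0).filled(np.nan) / 2.0)
    norm = normalized_af_diff(f_risk, f_ctrl)
    defined = ~np.isnan(norm) & ~np.isnan(overall)
    n_excluded = int((~defined).sum())
    if defined.sum() >= 3 and np.std(overall[defined]) > 0 \
            and np.std(norm[defined]) > 0:
        r, rp = stats.pearsonr(overall[defined], norm[defined])
        r, rp = float(r), float(rp)
        degenerate = False
    else:
        r, rp, degenerate = float("nan"), float("nan"), True
    return {
        "n_variants": int(len(f_risk)),
        "median_f_risk": float(np.median(f_risk)),
        "median_f_ctrl": float(np.median(f_ctrl)),
        "wilcoxon_stat": wstat, "wilcoxon_p": wp,
        "pearson_r": r, "pearson_p": rp,
        "n_excluded_norm": n_excluded,
        "flag_degenerate_correlation": degenerate,
        "f_risk": f_risk, "f_ctrl": f_ctrl,
        "overall_af": overall, "normalized_diff": norm,
    }
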