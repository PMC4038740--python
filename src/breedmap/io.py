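"""Readers and writers for the plain-text formats the pipeline exchanges.

VCF is read through cyvcf2; everything else is TSV/BED/GMT via pandas or
line-oriented code. All writers emit deterministic, byte-stable output for a
given input so simulation runs can be checksummed.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix, IntensityMatrix

GENO_CODES = {0: "0", 1: "1", 2: "2", MISSING: "NA"}


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def write_intensity_tsv(intens: IntensityMatrix, path) -> None:
    """Long-format TSV: sample, chip, snp, channelA, channelB."""
    n_s, n_p = intens.n_samples, intens.n_snps
    rows = {
        "sample": np.repeat(intens.samples["sample"].to_numpy(), n_p),
        "chip": np.repeat(intens.samples["chip"].to_numpy(), n_p),
        "snp": np.tile(intens.snps["id"].to_numpy(), n_s),
        "channelA": intens.values[:, :, 0].ravel(),
        "channelB": intens.values[:, :, 1].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_intensity_tsv(path, snps: pd.DataFrame) -> IntensityMatrix:
    df = pd.read_csv(path, sep="\t")
    samples = df[["sample", "chip"]].drop_duplicates().reset_index(drop=True)
    snp_ids = snps["id"].to_numpy()
    s_index = {s: i for i, s in enumerate(samples["sample"])}
    p_index = {p: i for i, p in enumerate(snp_ids)}
    values = np.zeros((len(samples), len(snp_ids), 2))
    si = df["sample"].map(s_index).to_numpy()
    pi = df["snp"].map(p_index).to_numpy()
    values[si, pi, 0] = df["channelA"].to_numpy()
    values[si, pi, 1] = df["channelB"].to_numpy()
    return IntensityMatrix(values, snps, samples)


# ---------------------------------------------------------------------------
# sample sheets and genotype TSV
# ---------------------------------------------------------------------------

def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotype_tsv(gm: GenotypeMatrix, geno_path, snp_map_path=None) -> None:
    """Sample x SNP table of codes 0/1/2/NA, plus an optional SNP map TSV."""
    codes = pd.DataFrame(
        np.vectorize(GENO_CODES.get)(gm.genotypes),
        index=gm.samples["sample"],
        columns=gm.snps["id"],
    )
    codes.index.name = "sample"
    codes.to_csv(geno_path, sep="\t")
    if snp_map_path is not None:
        gm.snps.to_csv(snp_map_path, sep="\t", index=False)


def read_genotype_tsv(geno_path, snp_map_path, sample_sheet_path) -> GenotypeMatrix:
    codes = pd.read_csv(geno_path, sep="\t", index_col="sample", dtype=str,
                        keep_default_na=False)
    snps = pd.read_csv(snp_map_path, sep="\t")
    samples = read_sample_sheet(sample_sheet_path)
    codes = codes.loc[samples["sample"], snps["id"].astype(str)]
    geno = codes.replace("NA", str(MISSING)).astype(np.int8).to_numpy()
    return GenotypeMatrix(geno, snps, samples)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _gq(conf: float) -> int:
    if conf >= 1.0:
        return 99
    return min(99, int(round(-10.0 * math.log10(max(1.0 - conf, 1e-10)))))


def write_vcf(gm: GenotypeMatrix, path, confidence: np.ndarray | None = None,
              contig_lengths: dict | None = None) -> None:
    """Write genotypes as minimal VCF 4.2 (GT, optionally GQ)."""
    fmt = "GT:GQ" if confidence is not None else "GT"
    lines = ["##fileformat=VCFv4.2", "##source=breedmap"]
    chroms = list(dict.fromkeys(gm.snps["chrom"]))
    for c in chroms:
        if contig_lengths and c in contig_lengths:
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if confidence is not None:
        lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                     'Description="Phred-scaled call confidence">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
    header[7:7] = ["INFO"]
    lines.append("\t".join(header + list(gm.samples["sample"].astype(str))))
    order = np.lexsort((gm.snps["pos"].to_numpy(),
                        gm.snps["chrom"].astype(str).to_numpy()))
    for j in order:
        snp = gm.snps.iloc[j]
        fields = [str(snp["chrom"]), str(int(snp["pos"]) + 1), str(snp["id"]),
                  str(snp["ref"]), str(snp["alt"]), ".", "PASS", ".", fmt]
        for i in range(gm.n_samples):
            g = _GT_STRINGS[int(gm.genotypes[i, j])]
            if confidence is not None:
                g = f"{g}:{_gq(float(confidence[i, j]))}"
            fields.append(g)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, samples: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a (possibly uncompressed) VCF into a GenotypeMatrix.

    If ``samples`` is given it must carry a ``sample`` column matching the
    VCF sample names; rows are aligned to VCF order.
    """
    vcf = VCF(str(path), gts012=True)
    names = list(vcf.samples)
    recs = {"id": [], "chrom": [], "pos": [], "ref": [], "alt": []}
    geno_rows = []
    for var in vcf:
        recs["id"].append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        recs["chrom"].append(var.CHROM)
        recs["pos"].append(var.POS - 1)  # back to 0-based
        recs["ref"].append(var.REF)
        recs["alt"].append(var.ALT[0] if var.ALT else ".")
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        gt[gt == 3] = MISSING
        geno_rows.append(gt)
    vcf.close()
    snps = pd.DataFrame(recs)
    geno = (np.stack(geno_rows, axis=1) if geno_rows
            else np.zeros((len(names), 0), dtype=np.int8))
    if samples is None:
        samples = pd.DataFrame({"sample": names})
    else:
        samples = samples.set_index("sample").loc[names].reset_index()
    return GenotypeMatrix(geno, snps, samples)


# ---------------------------------------------------------------------------
# BED / GMT
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path, extra_cols=()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
            row = parts[: len(names)] + [None] * max(0, len(names) - len(parts))
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(names))
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, name, *sets[name]]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets
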