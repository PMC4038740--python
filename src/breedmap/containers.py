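"""In-memory containers shared across the pipeline.

Conventions
-----------
* Genotypes are coded as the alternate-allele dosage 0/1/2, with -1 for
  missing, stored as ``int8`` arrays of shape (n_samples, n_snps).
* All genomic coordinates are 0-based half-open internally; VCF output is
  1-based as the format requires.
* Sample sheets carry ``sample``, ``breed``, ``group`` (case/control/unknown)
  and, for genotyping panels, ``breed_class`` (risk/control_breed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SNP_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Coded genotypes with SNP map and sample metadata.

    Attributes
    ----------
    genotypes : int8 array, (n_samples, n_snps)
        Alt-allele dosage; ``MISSING`` (-1) marks a failed call.
    snps : DataFrame with columns ``id, chrom, pos, ref, alt``
    samples : DataFrame with at least ``sample``; usually ``breed, group, chip``
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def called_mask(self) -> np.ndarray:
        return self.genotypes != MISSING

    def snp_call_rate(self) -> np.ndarray:
        return self.called_mask().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return self.called_mask().mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls (NaN if none)."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        with np.errstate(invalid="ignore"):
            freq = g.mean(axis=0).filled(np.nan) / 2.0
        return freq

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            self.genotypes[np.ix_(sample_idx, snp_idx)],
            self.snps.iloc[snp_idx],
            self.samples.iloc[sample_idx],
        )

    def by_breed(self, breed: str) -> "GenotypeMatrix":
        idx = np.flatnonzero((self.samples["breed"] == breed).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no samples from breed {breed!r}")
        return self.subset(sample_idx=idx)


@dataclass
class IntensityMatrix:
    """Two-channel fluorescence intensities per sample and SNP.

    ``values`` has shape (n_samples, n_snps, 2) with channels (A, B);
    intensities are non-negative in arbitrary units. Each sample carries a
    chip label in ``samples['chip']``.
    """

    values: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 2:
            raise ValueError("intensity values must have shape (samples, snps, 2)")
        if self.values.shape[:2] != (len(self.samples), len(self.snps)):
            raise ValueError("intensity array does not match sample/SNP tables")
        if np.any(self.values < 0):
            raise ValueError("negative intensities are not allowed")
        if "chip" not in self.samples.columns:
            raise ValueError("samples table must carry a 'chip' column")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class CallSet:
    """Genotype calls with per-call posterior confidence and cluster params.

    ``params`` maps snp index -> dict with keys ``means`` (k x 2), ``scales``
    (k x 2 x 2), ``weights`` (k,), ``df``, ``converged``, ``flagged``.
    """

    genotypes: np.ndarray
    confidence: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame
    params: dict = field(default_factory=dict)
    no_call_threshold: float = 0.95

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.confidence = np.asarray(self.confidence, dtype=float)

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.genotypes.copy(), self.snps, self.samples)


@dataclass
class RegionSet:
    """Labeled, scored genomic intervals (half-open) with member SNP ids."""

    regions: pd.DataFrame  # columns: chrom, start, end, label, score
    members: dict = field(default_factory=dict)  # label -> list of snp ids

    REQUIRED = ["chrom", "start", "end", "label", "score"]

    def __post_init__(self) -> None:
        if len(self.regions) == 0:
            self.regions = pd.DataFrame(columns=self.REQUIRED)
        missing = [c for c in self.REQUIRED if c not in self.regions.columns]
        if missing:
            raise ValueError(f"region table missing columns {missing}")
        bad = self.regions["start"] >= self.regions["end"]
        if bad.any():
            raise ValueError("regions must satisfy start < end")
        self.regions = self.regions.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.regions)

    def validate_disjoint(self) -> None:
        for chrom, sub in self.regions.groupby("chrom"):
            sub = sub.sort_values("start")
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping regions on {chrom}")


# A VariantTable is a plain DataFrame with one row per variant:
#   chrom, pos, ref, alt, vclass (SNP/INDEL/deletion), consequence,
#   constrained (bool), gene (may be ''), status
# plus one int8 dosage column per sequenced dog (0/1/2, -1 missing).
VARIANT_META_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vclass", "consequence", "constrained", "gene",
]


def variant_dog_columns(table: pd.DataFrame) -> list[str]:
    """Names of the per-dog genotype columns of a variant table."""
    skip = set(VARIANT_META_COLUMNS) | {"status", "id"}
    return [c for c in table.columns if c not in skip]


@dataclass
class BreedPanel:
    """Per-variant genotypes for the breed genotyping panel.

    ``genotypes`` is (n_dogs, n_variants) dosage with -1 missing; ``samples``
    carries ``breed_class`` in {risk, control_breed}.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError("panel genotype array does not match tables")
        if "breed_class" not in self.samples.columns:
            raise ValueError("panel sample sheet needs a 'breed_class' column")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    def group_freq(self, breed_class: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["breed_class"] == breed_class).to_numpy())
        g = np.ma.masked_equal(self.genotypes[idx], MISSING)
        with np.errstate(invalid="ignore"):
            return g.mean(axis=0).filled(np.nan) / 2.0
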