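"""Synthetic breed-structured data with planted ground truth.

Every input the mapping pipeline consumes can be generated here: multi-breed
allele frequencies under the Balding-Nichols model, Hardy-Weinberg genotypes
with planted associated loci, two-channel array intensities with chip batch
effects and heavy-tailed noise, a targeted-sequencing variant table with
case-only variants concentrated in designated genes, and a breed genotyping
panel with a planted risk/control frequency contrast.

The defaults emulate the study design this package reimplements: ~200
genotyped dogs from strongly differentiated breeds (F_ST = 0.2), an
8-case / 8-control sequencing panel drawn from four breeds, four genes
carrying 10/16/12/16 case-only variants, and a genotyping panel of 94 dogs
and 127 variants that shrinks to 88 dogs and 114 variants after QC.

All randomness flows from ``SimulationConfig.seed``; a given config is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, BreedPanel, GenotypeMatrix, IntensityMatrix

CHROM = "chr1"

# genotype cluster means in (A, B) channel space: hom-ref, het, hom-alt
DEFAULT_CLUSTER_MEANS = ((2.0, 0.2), (1.1, 1.1), (0.2, 2.0))


@dataclass
class IntensityModel:
    """Two-channel emission model for array intensities.

    ``noise_scale`` is the scale parameter of the bivariate t noise added to
    the cluster mean of the true genotype; ``chip_factors`` multiply all
    intensities of a chip (batch effect). The default noise scale puts the
    minimal between-cluster distance at ~10x the noise scale, which yields
    the >90% per-SNP call rates and ~99.5% concordance real arrays show; a
    harsher 6x stress setting is noise_scale=0.212.
    """

    cluster_means: tuple = DEFAULT_CLUSTER_MEANS
    noise_scale: float = 0.13
    t_df: float = 5.0
    chip_factors: tuple = (1.0, 1.3)

    def validate(self) -> None:
        m = np.asarray(self.cluster_means, dtype=float)
        if m.shape != (3, 2):
            raise ValueError("cluster_means must be 3 genotype means in 2 channels")
        d01 = np.linalg.norm(m[0] - m[1])
        d12 = np.linalg.norm(m[1] - m[2])
        d02 = np.linalg.norm(m[0] - m[2])
        if min(d01, d12, d02) < 1e-9:
            raise ValueError("cluster means must be pairwise distinct")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.t_df <= 2:
            raise ValueError("t_df must exceed 2 for finite noise variance")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Planted features are expressed in 0-based half-open coordinates on a
    single chromosome. ``planted_assoc`` entries are
    (position, case allele frequency, control allele frequency);
    ``planted_fixed_region`` is (start, end, max MAF) in the first (target)
    breed; ``planted_decoy_region`` is a sub-megabase near-fixed region that
    must never satisfy the fixation rule; ``planted_rrv_region`` is
    (start, end, heterozygosity scale) shrinking target-breed heterozygosity;
    ``planted_burden_genes`` are (gene id, n case-only, n control-only).
    """

    seed: int = 0
    n_breeds: int = 4
    n_per_breed: int = 50
    n_snps: int = 1000
    fst: float = 0.2
    chrom_length: int = 100_000_000
    missing_rate: float = 0.01
    case_fraction: float = 0.5
    planted_assoc: tuple = ((25_000_000, 0.6, 0.2),)
    planted_fixed_region: tuple = (40_000_000, 41_500_000, 0.01)
    planted_decoy_region: tuple = (70_000_000, 70_900_000, 0.01)
    # at the chromosome start: zero-het windows tie at score 0 with windows
    # inside fixation regions, and ties resolve to the earliest window
    planted_rrv_region: tuple = (0, 150_000, 0.0)
    planted_burden_genes: tuple = (
        ("ATXN1L", 10, 2), ("CDH2L", 16, 2), ("CTNNA2L", 12, 3), ("PGCPL", 16, 3),
    )
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    # gene / set catalog geometry
    n_genes: int = 60
    n_gene_sets: int = 40
    # sequencing panel: dogs per breed as (cases, controls)
    seq_design: tuple = ((4, 4), (2, 2), (1, 1), (1, 1))
    n_background_variants: int = 300
    constrained_fraction: float = 0.8
    # genotyping panel (breed frequency contrast)
    # 94 genotyped dogs and 127 designed variants; the planted QC failures
    # (5 risk + 1 control dog, 13 variants) leave 88 dogs x 114 variants
    panel_n_variants: int = 127
    panel_n_risk_dogs: int = 74
    panel_n_control_dogs: int = 20
    panel_n_bad_snps: int = 13
    panel_n_bad_dogs: int = 6

    def validate(self) -> None:
        for name in ("n_breeds", "n_per_breed", "n_snps", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must lie in (0, 1), got {self.fst}")
        for start, end, _ in (self.planted_fixed_region, self.planted_decoy_region,
                              self.planted_rrv_region):
            if not (0 <= start < end <= self.chrom_length):
                raise ValueError("planted region outside [0, chrom_length)")
        for pos, fa, fu in self.planted_assoc:
            if not 0 <= pos < self.chrom_length:
                raise ValueError("planted association position outside chromosome")
            if not (0 <= fa <= 1 and 0 <= fu <= 1):
                raise ValueError("planted association frequencies must be in [0,1]")
        self.intensity_model.validate()

    @property
    def breeds(self) -> list[str]:
        return [f"breed{i + 1}" for i in range(self.n_breeds)]

    def rng(self, stage: int) -> np.random.Generator:
        """Independent stream for a pipeline stage, derived from the seed."""
        return np.random.default_rng([int(self.seed) % (2**31), stage])


# ---------------------------------------------------------------------------
# SNP map
# ---------------------------------------------------------------------------

N_FIXED_SNPS = 20
N_DECOY_SNPS = 10
N_RRV_SNPS = 10
GUARD_OFFSETS = (10_000, 25_000, 40_000)  # polymorphic guards around the decoy


def snp_map(config: SimulationConfig) -> pd.DataFrame:
    """SNP positions with guaranteed coverage of every planted feature.

    Planted regions receive fixed blocks of evenly spaced SNPs so that the
    fixation / RRV criteria are decidable regardless of the random draw; the
    decoy region is ringed by guard SNPs kept polymorphic so it can never be
    extended past the 1 Mb span threshold.
    """
    config.validate()
    rng = config.rng(1)
    reserved: list[tuple[int, str]] = []
    for pos, _, _ in config.planted_assoc:
        reserved.append((int(pos), "assoc"))
    fs, fe, _ = config.planted_fixed_region
    for p in np.linspace(fs, fe - 1, N_FIXED_SNPS).astype(int):
        reserved.append((int(p), "fixed"))
    ds, de, _ = config.planted_decoy_region
    for p in np.linspace(ds, de - 1, N_DECOY_SNPS).astype(int):
        reserved.append((int(p), "decoy"))
    for off in GUARD_OFFSETS:
        if ds - off >= 0:
            reserved.append((ds - off, "guard"))
        if de + off < config.chrom_length:
            reserved.append((de + off, "guard"))
    rs, re_, _ = config.planted_rrv_region
    for p in np.linspace(rs, re_ - 1, N_RRV_SNPS).astype(int):
        reserved.append((int(p), "rrv"))

    seen: set[int] = set()
    reserved = [(p, t) for p, t in reserved
                if not (p in seen or seen.add(p))]
    n_random = max(0, config.n_snps - len(reserved))
    taken = {p for p, _ in reserved}
    # keep random SNPs out of the guard ring so decoy geometry stays planted
    lo, hi = ds - max(GUARD_OFFSETS) - 10_000, de + max(GUARD_OFFSETS) + 10_000
    positions = []
    while len(positions) < n_random:
        draw = rng.integers(0, config.chrom_length, size=n_random)
        for p in draw:
            p = int(p)
            if lo <= p < hi or p in taken:
                continue
            taken.add(p)
            positions.append(p)
            if len(positions) == n_random:
                break
    allpos = sorted([(p, "bg") for p in positions] + reserved)
    df = pd.DataFrame({
        "id": [f"snp{i + 1}" for i in range(len(allpos))],
        "chrom": CHROM,
        "pos": [p for p, _ in allpos],
        "ref": "A",
        "alt": "B",
        "tag": [t for _, t in allpos],
    })
    return df


# ---------------------------------------------------------------------------
# breed allele frequencies (Balding-Nichols)
# ---------------------------------------------------------------------------

def simulate_breed_frequencies(config: SimulationConfig,
                               snps: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-breed alt-allele frequencies under the Balding-Nichols model.

    Ancestral frequency p ~ U(0.05, 0.95) per SNP; each breed draws from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = config.fst, so breed frequencies
    have mean p and variance F p(1-p). Planted regions overwrite the draw in
    the first (target) breed.

    Returns a DataFrame with the SNP map columns plus ``ancestral`` and one
    frequency column per breed.
    """
    config.validate()
    if snps is None:
        snps = snp_map(config)
    rng = config.rng(2)
    n = len(snps)
    p = rng.uniform(0.05, 0.95, size=n)
    f = config.fst
    shape = (1.0 - f) / f
    freqs = {}
    for breed in config.breeds:
        freqs[breed] = rng.beta(p * shape, (1.0 - p) * shape)
    out = snps.copy()
    out["ancestral"] = p
    for breed in config.breeds:
        out[breed] = freqs[breed]

    target = config.breeds[0]
    pos = out["pos"].to_numpy()
    for (start, end, max_maf) in (config.planted_fixed_region,
                                  config.planted_decoy_region):
        inside = (pos >= start) & (pos < end)
        k = int(inside.sum())
        low = rng.uniform(0.0, max_maf, size=k)
        side = rng.integers(0, 2, size=k)
        out.loc[inside, target] = np.where(side == 1, 1.0 - low, low)
    rs, re_, het_scale = config.planted_rrv_region
    inside = (pos >= rs) & (pos < re_)
    orig = out.loc[inside, target].to_numpy()
    nearest = np.round(orig)
    out.loc[inside, target] = het_scale * orig + (1.0 - het_scale) * nearest
    guards = (out["tag"] == "guard").to_numpy()
    out.loc[guards, target] = 0.35
    return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    n_chips = len(config.intensity_model.chip_factors)
    i = 0
    for breed in config.breeds:
        n_cases = int(round(config.case_fraction * config.n_per_breed))
        for j in range(config.n_per_breed):
            rows.append({
                "sample": f"{breed}_d{j + 1}",
                "breed": breed,
                "group": "case" if j < n_cases else "control",
                "chip": f"chip{i % n_chips + 1}",
            })
            i += 1
    return pd.DataFrame(rows)


def simulate_genotypes(freqs: pd.DataFrame, config: SimulationConfig) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes per breed, with planted associated loci.

    At planted association positions the alt-allele frequency is taken from
    the case/control planted values (identical across breeds); everywhere
    else each dog draws Binomial(2, breed frequency). Missing calls are
    injected at ``config.missing_rate``.
    """
    config.validate()
    rng = config.rng(3)
    samples = _sample_sheet(config)
    n_snps = len(freqs)
    geno = np.zeros((len(samples), n_snps), dtype=np.int8)
    for breed in config.breeds:
        idx = np.flatnonzero((samples["breed"] == breed).to_numpy())
        bf = freqs[breed].to_numpy()
        geno[idx] = rng.binomial(2, bf[None, :], size=(idx.size, n_snps))
    pos = freqs["pos"].to_numpy()
    is_case = (samples["group"] == "case").to_numpy()
    for (p, f_case, f_ctrl) in config.planted_assoc:
        j = int(np.flatnonzero(pos == int(p))[0])
        geno[is_case, j] = rng.binomial(2, f_case, size=int(is_case.sum()))
        geno[~is_case, j] = rng.binomial(2, f_ctrl, size=int((~is_case).sum()))
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = MISSING
    snps = freqs[["id", "chrom", "pos", "ref", "alt"]].copy()
    return GenotypeMatrix(geno, snps, samples)


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def simulate_intensities(truth: GenotypeMatrix,
                         config: SimulationConfig) -> IntensityMatrix:
    """Two-channel intensities from true genotypes.

    Each (sample, SNP) point is the cluster mean of the true genotype plus
    bivariate t noise (independent axes, fixed df), all scaled by the
    sample's chip factor. Missing true genotypes emit from the het cluster
    (the array measures them regardless). Intensities are clipped at zero.
    """
    model = config.intensity_model
    model.validate()
    rng = config.rng(4)
    means = np.asarray(model.cluster_means, dtype=float)
    g = truth.genotypes.copy()
    g[g == MISSING] = 1
    base = means[g]  # (n_samples, n_snps, 2)
    if model.noise_scale > 0:
        noise = model.noise_scale * rng.standard_t(model.t_df, size=base.shape)
    else:
        noise = 0.0
    chip_ids = truth.samples["chip"].to_numpy()
    chips = [f"chip{i + 1}" for i in range(len(model.chip_factors))]
    factor = np.array([model.chip_factors[chips.index(c)] for c in chip_ids])
    values = np.clip((base + noise) * factor[:, None, None], 0.0, None)
    return IntensityMatrix(values, truth.snps, truth.samples)


# ---------------------------------------------------------------------------
# gene catalog, gene sets, constrained elements
# ---------------------------------------------------------------------------

def gene_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Non-overlapping genes tiling the chromosome, planted genes included.

    The planted burden genes are placed in the second half of the chromosome,
    away from the planted association locus, so burden counts are not
    confounded with association regions.
    """
    rng = config.rng(5)
    planted = [g for g, _, _ in config.planted_burden_genes]
    n_random = max(0, config.n_genes - len(planted))
    slots = np.linspace(0, config.chrom_length * 0.98, config.n_genes + 1).astype(int)
    lengths = rng.integers(20_000, 200_000, size=config.n_genes)
    names = [f"G{i + 1:03d}" for i in range(n_random)]
    # planted genes occupy evenly spaced slots in the second half
    planted_slots = np.linspace(config.n_genes // 2, config.n_genes - 1,
                                len(planted)).astype(int)
    all_names = list(names)
    for s, g in zip(planted_slots, planted):
        all_names.insert(min(s, len(all_names)), g)
    rows = []
    for i, name in enumerate(all_names[: config.n_genes]):
        start = int(slots[i]) + 5_000
        end = min(start + int(lengths[i]), config.chrom_length - 1)
        rows.append({"chrom": CHROM, "start": start, "end": end, "name": name})
    df = pd.DataFrame(rows).sort_values("start").reset_index(drop=True)
    return df


def gene_sets(catalog: pd.DataFrame, config: SimulationConfig) -> dict[str, list[str]]:
    """Random gene sets (sizes 5-30) plus one set of genes near planted loci."""
    rng = config.rng(6)
    genes = catalog["name"].tolist()
    sets: dict[str, list[str]] = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(5, 31))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        sets[f"SET{i + 1:03d}"] = sorted(members.tolist())
    # a set concentrated near the planted association locus
    if config.planted_assoc:
        pos = config.planted_assoc[0][0]
        near = catalog.loc[
            (catalog["start"] < pos + 2_000_000)
            & (catalog["end"] > pos - 2_000_000), "name"].tolist()
        pad = [g for g in genes if g not in near][: max(0, 5 - len(near))]
        sets["SET_PLANTED"] = sorted(near + pad)
    return sets


def constrained_elements(config: SimulationConfig,
                         catalog: pd.DataFrame) -> pd.DataFrame:
    """Constrained-element intervals: several per gene plus intergenic ones."""
    rng = config.rng(7)
    rows = []
    for _, g in catalog.iterrows():
        n_el = int(rng.integers(2, 5))
        for _ in range(n_el):
            span = g["end"] - g["start"]
            start = int(g["start"] + rng.integers(0, max(1, span - 200)))
            rows.append({"chrom": CHROM, "start": start,
                         "end": min(start + int(rng.integers(50, 400)), config.chrom_length)})
    for _ in range(config.n_genes):
        start = int(rng.integers(0, config.chrom_length - 500))
        rows.append({"chrom": CHROM, "start": start,
                     "end": start + int(rng.integers(50, 400))})
    df = pd.DataFrame(rows).sort_values("start").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# targeted-sequencing variant table
# ---------------------------------------------------------------------------

def seq_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """The sequencing panel: (cases, controls) per breed per ``seq_design``."""
    rows = []
    for b, (n_case, n_ctrl) in enumerate(config.seq_design):
        breed = config.breeds[b % config.n_breeds]
        for j in range(n_case):
            rows.append({"sample": f"{breed}_case{j + 1}", "breed": breed,
                         "group": "case"})
        for j in range(n_ctrl):
            rows.append({"sample": f"{breed}_ctrl{j + 1}", "breed": breed,
                         "group": "control"})
    return pd.DataFrame(rows)


def _place_in_elements(rng, n, lo, hi, elements):
    """n positions in [lo, hi), preferring the given constrained elements."""
    inside = [(max(s, lo), min(e, hi)) for s, e in elements if max(s, lo) < min(e, hi)]
    out = []
    for i in range(n):
        if inside:
            s, e = inside[int(rng.integers(0, len(inside)))]
            out.append(int(rng.integers(s, e)))
        else:
            out.append(int(rng.integers(lo, hi)))
    return out


def simulate_variant_table(config: SimulationConfig, catalog: pd.DataFrame,
                           constrained: pd.DataFrame):
    """Sequencing variant table with planted case-only burden.

    Background variants are shared between the groups and avoid the planted
    genes' +/-5 kb neighbourhoods, so the planted per-gene counts are exact.
    For each planted gene the stated numbers of case-only and control-only
    variants are emitted with a ``constrained_fraction`` share placed inside
    constrained elements. One case-only frameshift deletion is always
    planted in the last burden gene (emulating a structural loss).

    Returns (variant table, sequencing sample sheet, truth table).
    """
    rng = config.rng(8)
    dogs = seq_sample_sheet(config)
    catalog = catalog.set_index("name")
    missing = [g for g, _, _ in config.planted_burden_genes if g not in catalog.index]
    if missing:
        raise KeyError(f"planted burden genes not in catalog: {missing}")
    case_dogs = dogs.loc[dogs["group"] == "case", "sample"].tolist()
    ctrl_dogs = dogs.loc[dogs["group"] == "control", "sample"].tolist()
    all_dogs = dogs["sample"].tolist()
    elements = list(zip(constrained["start"], constrained["end"]))

    flank = 5_000
    forbidden = [(catalog.loc[g, "start"] - flank, catalog.loc[g, "end"] + flank)
                 for g, _, _ in config.planted_burden_genes]

    rows, truth_rows = [], []

    def genotype_row(carriers):
        gt = {d: 0 for d in all_dogs}
        for d in carriers:
            gt[d] = int(rng.integers(1, 3))
        return gt

    # background shared variants
    n_bg = config.n_background_variants
    placed = 0
    while placed < n_bg:
        p = int(rng.integers(0, config.chrom_length))
        if any(lo <= p < hi for lo, hi in forbidden):
            continue
        # carriers drawn from the whole panel: most background variants are
        # shared, a minority is case- or control-only by chance (the null
        # "noise" a zero-burden table should show)
        n_carriers = int(rng.integers(1, len(all_dogs) + 1))
        carriers = list(rng.choice(all_dogs, n_carriers, replace=False))
        cons = any(s <= p < e for s, e in elements)
        rows.append({"chrom": CHROM, "pos": p, "ref": "A", "alt": "T",
                     "vclass": "SNP",
                     "consequence": str(rng.choice(
                         ["noncoding", "silent", "UTR", "missense"],
                         p=[0.6, 0.2, 0.1, 0.1])),
                     "constrained": cons, "gene": "",
                     **genotype_row(carriers)})
        truth_rows.append({"pos": p, "gene": "", "planted_status": "shared"})
        placed += 1

    # planted burden variants
    last_gene = (config.planted_burden_genes[-1][0]
                 if config.planted_burden_genes else None)
    for gene, n_case_only, n_ctrl_only in config.planted_burden_genes:
        gs, ge = int(catalog.loc[gene, "start"]), int(catalog.loc[gene, "end"])
        lo, hi = gs - flank, ge + flank
        n_cons_case = int(round(config.constrained_fraction * n_case_only))
        for k in range(n_case_only):
            in_cons = k < n_cons_case
            p = (_place_in_elements(rng, 1, lo, hi, elements)[0] if in_cons
                 else _pos_outside_elements(rng, lo, hi, elements))
            carriers = list(rng.choice(case_dogs,
                                       min(int(rng.integers(1, 6)), len(case_dogs)),
                                       replace=False))
            vclass, conseq = "SNP", "noncoding"
            if gene == last_gene and k == 0:
                vclass, conseq = "deletion", "frameshift"
            rows.append({"chrom": CHROM, "pos": p, "ref": "A", "alt": "T",
                         "vclass": vclass, "consequence": conseq,
                         "constrained": any(s <= p < e for s, e in elements),
                         "gene": gene, **genotype_row(carriers)})
            truth_rows.append({"pos": p, "gene": gene,
                               "planted_status": "case-only"})
        n_cons_ctrl = int(round(config.constrained_fraction * n_ctrl_only))
        for k in range(n_ctrl_only):
            in_cons = k < n_cons_ctrl
            p = (_place_in_elements(rng, 1, lo, hi, elements)[0] if in_cons
                 else _pos_outside_elements(rng, lo, hi, elements))
            carriers = list(rng.choice(ctrl_dogs,
                                       min(int(rng.integers(1, 6)), len(ctrl_dogs)),
                                       replace=False))
            rows.append({"chrom": CHROM, "pos": p, "ref": "A", "alt": "T",
                         "vclass": "SNP", "consequence": "noncoding",
                         "constrained": any(s <= p < e for s, e in elements),
                         "gene": gene, **genotype_row(carriers)})
            truth_rows.append({"pos": p, "gene": gene,
                               "planted_status": "control-only"})

    table = pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)
    table.insert(0, "id", [f"var{i + 1}" for i in range(len(table))])
    truth = pd.DataFrame(truth_rows).sort_values("pos").reset_index(drop=True)
    return table, dogs, truth


def _pos_outside_elements(rng, lo, hi, elements):
    for _ in range(1000):
        p = int(rng.integers(lo, hi))
        if not any(s <= p < e for s, e in elements):
            return p
    return int(rng.integers(lo, hi))


# ---------------------------------------------------------------------------
# breed genotyping panel
# ---------------------------------------------------------------------------

def simulate_breed_panel(config: SimulationConfig) -> BreedPanel:
    """Genotyping panel contrasting risk and control breed groups.

    Per-variant control-breed frequencies are U(0, 0.10) (median 0.05); risk
    frequencies add +0.12 on variants rare in control breeds, emulating
    case-only variants that are common in risk breeds (median ~0.17) yet rare
    overall. A fixed number of dogs and variants are planted to fail the
    genotyping QC thresholds (10% sample missingness, 90% SNP call rate).
    """
    rng = config.rng(9)
    n_var = config.panel_n_variants
    f_ctrl = rng.uniform(0.0, 0.10, size=n_var)
    f_risk = np.clip(f_ctrl + np.where(f_ctrl < 0.10, 0.12, 0.0), 0.0, 1.0)
    n_risk, n_ctrl = config.panel_n_risk_dogs, config.panel_n_control_dogs
    g_risk = rng.binomial(2, f_risk[None, :], size=(n_risk, n_var))
    g_ctrl = rng.binomial(2, f_ctrl[None, :], size=(n_ctrl, n_var))
    geno = np.concatenate([g_risk, g_ctrl]).astype(np.int8)
    samples = pd.DataFrame({
        "sample": [f"risk_d{i + 1}" for i in range(n_risk)]
                  + [f"ctrl_d{i + 1}" for i in range(n_ctrl)],
        "breed": ["riskbreed"] * n_risk + ["ctrlbreed"] * n_ctrl,
        "group": "unknown",
        "breed_class": ["risk"] * n_risk + ["control_breed"] * n_ctrl,
    })
    miss = rng.random(geno.shape) < 0.01
    # planted QC failures: risk dogs first, one control dog, last SNPs
    n_bad_risk = max(0, config.panel_n_bad_dogs - 1)
    bad_dogs = np.concatenate([np.arange(n_bad_risk),
                               [n_risk]])[:config.panel_n_bad_dogs].astype(int)
    miss[bad_dogs] |= rng.random((len(bad_dogs), n_var)) < 0.25
    bad_snps = np.arange(n_var - config.panel_n_bad_snps, n_var)
    miss[:, bad_snps] |= rng.random((geno.shape[0], len(bad_snps))) < 0.25
    geno[miss] = MISSING
    variants = pd.DataFrame({
        "id": [f"pvar{i + 1}" for i in range(n_var)],
        "chrom": CHROM,
        "pos": np.sort(rng.choice(config.chrom_length, size=n_var, replace=False)),
        "ref": "A", "alt": "T",
    })
    return BreedPanel(geno, variants, samples)


# ---------------------------------------------------------------------------
# one-call dataset + on-disk emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    freqs: pd.DataFrame
    truth_genotypes: GenotypeMatrix
    intensities: IntensityMatrix
    catalog: pd.DataFrame
    sets: dict
    constrained: pd.DataFrame
    variant_table: pd.DataFrame
    seq_dogs: pd.DataFrame
    variant_truth: pd.DataFrame
    panel: BreedPanel


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic study from one config."""
    config = config or SimulationConfig()
    config.validate()
    freqs = simulate_breed_frequencies(config)
    truth = simulate_genotypes(freqs, config)
    intens = simulate_intensities(truth, config)
    catalog = gene_catalog(config)
    sets = gene_sets(catalog, config)
    cons = constrained_elements(config, catalog)
    table, seq_dogs, var_truth = simulate_variant_table(config, catalog, cons)
    panel = simulate_breed_panel(config)
    return SyntheticDataset(config, freqs, truth, intens, catalog, sets, cons,
                            table, seq_dogs, var_truth, panel)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Emit every pipeline input as plain text; returns {name: path}."""
    from pathlib import Path

    from . import io as bio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    cfg = ds.config

    paths["intensities"] = str(out / "intensities.tsv")
    bio.write_intensity_tsv(ds.intensities, paths["intensities"])
    paths["samples"] = str(out / "samples.tsv")
    bio.write_sample_sheet(ds.truth_genotypes.samples, paths["samples"])
    paths["truth_genotypes"] = str(out / "truth_genotypes.tsv")
    paths["snp_map"] = str(out / "snp_map.tsv")
    bio.write_genotype_tsv(ds.truth_genotypes, paths["truth_genotypes"],
                           paths["snp_map"])
    paths["genotypes_vcf"] = str(out / "truth_genotypes.vcf")
    bio.write_vcf(ds.truth_genotypes, paths["genotypes_vcf"],
                  contig_lengths={CHROM: cfg.chrom_length})
    paths["genes"] = str(out / "genes.bed")
    bio.write_bed(ds.catalog, paths["genes"], extra_cols=("name",))
    paths["constrained"] = str(out / "constrained.bed")
    bio.write_bed(ds.constrained, paths["constrained"])
    paths["gene_sets"] = str(out / "gene_sets.gmt")
    bio.write_gmt(ds.sets, paths["gene_sets"])
    paths["variants"] = str(out / "variants.tsv")
    ds.variant_table.to_csv(paths["variants"], sep="\t", index=False)
    paths["seq_samples"] = str(out / "seq_samples.tsv")
    bio.write_sample_sheet(ds.seq_dogs, paths["seq_samples"])
    paths["panel_genotypes"] = str(out / "panel_genotypes.tsv")
    panel_gm = GenotypeMatrix(ds.panel.genotypes, ds.panel.variants,
                              ds.panel.samples)
    paths["panel_variants"] = str(out / "panel_variants.tsv")
    bio.write_genotype_tsv(panel_gm, paths["panel_genotypes"],
                           paths["panel_variants"])
    paths["panel_samples"] = str(out / "panel_samples.tsv")
    bio.write_sample_sheet(ds.panel.samples, paths["panel_samples"])

    truth_rows = []
    for pos, fc, fu in cfg.planted_assoc:
        truth_rows.append(("assoc_locus", str(pos), f"{fc}/{fu}"))
    truth_rows.append(("fixed_region", f"{cfg.planted_fixed_region[0]}-"
                       f"{cfg.planted_fixed_region[1]}",
                       str(cfg.planted_fixed_region[2])))
    truth_rows.append(("decoy_region", f"{cfg.planted_decoy_region[0]}-"
                       f"{cfg.planted_decoy_region[1]}",
                       str(cfg.planted_decoy_region[2])))
    truth_rows.append(("rrv_region", f"{cfg.planted_rrv_region[0]}-"
                       f"{cfg.planted_rrv_region[1]}",
                       str(cfg.planted_rrv_region[2])))
    for g, nc, nk in cfg.planted_burden_genes:
        truth_rows.append(("burden_gene", g, f"{nc}/{nk}"))
    truth = pd.DataFrame(truth_rows, columns=["kind", "key", "value"])
    paths["truth"] = str(out / "truth.tsv")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["variant_truth"] = str(out / "variant_truth.tsv")
    ds.variant_truth.to_csv(paths["variant_truth"], sep="\t", index=False)
    return paths
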