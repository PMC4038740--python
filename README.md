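# breedmap

Mapping disease loci in breed-structured dog populations: a tested,
end-to-end reimplementation of the analysis workflow used to map canine
compulsive-disorder risk loci, exercised on synthetic data with planted
ground truth.

Dog breeds are closed populations with long haplotypes and strong
differentiation, which makes three complementary mapping strategies
unusually powerful: small case/control GWAS within a breed, scans for
breed-specific fixation and reduced variability (footprints of breed
formation and selection), and targeted sequencing of candidate regions in a
handful of affected and unaffected dogs, ranking variants that appear
*only* in cases. `breedmap` implements each stage as a library with a thin
command-line layer:

- **Genotype calling from array intensities** (`breedmap.caller`):
  per-chip quantile normalization with cross-chip alignment, per-SNP PCA of
  the two-channel intensity cloud, EM fitting of a 3-component bivariate
  *t* mixture (fixed ν), allele-contrast mapping of components to dosages
  0/1/2, posterior-threshold no-calls, and PLINK-style cohort QC
  (SNP call rate > 90 %, sample call rate > 25 %, MAF > 5 %).
- **Association and LD clumping** (`breedmap.assoc`): 1-df allelic
  chi-squared on 2×2 allele tables; greedy clumping of SNPs with
  P < 10⁻⁴ absorbing neighbours within 1 Mb with r² > 0.8 and P < 0.01;
  ±500 kb region-to-gene expansion.
- **Selection scans** (`breedmap.scans`): fixation regions (maximal
  intervals > 1 Mb, > 5 SNPs, > 95 % of SNPs at MAF < 0.05), regions of
  reduced variability (the 1 % least-variable 150 kb windows by expected
  heterozygosity 2p(1−p), relative to reference breeds), and cross-breed
  differential gene-set scoring.
- **Interval-permutation gene-set enrichment** (`breedmap.enrich`): the
  statistic per set is the number of candidate regions containing a set
  gene; the null relocates regions preserving their length and overlapped
  gene count (±1), controlling region size and gene density; add-one
  empirical P, min-P corrected P, and a meta-P for the excess of sets
  below P < 0.01.
- **Case-only burden** (`breedmap.burden`): case-only/control-only variant
  classification with explicit call-rate requirements, constrained-element
  intersection, exact per-dog rank-sum comparisons, per-gene burden in
  gene ± 5 kb with the pseudocounted ratio (case+1)/(control+1),
  leave-breed-out re-analysis, the six follow-up genotyping criteria, panel
  QC (missingness > 10 %, call rate < 90 %), and the bounded frequency
  contrast (AF_risk − AF_ctrl)/(AF_risk + AF_ctrl) with its correlation
  against overall allele frequency.
- **Synthetic data with planted truth** (`breedmap.simulate`): breed
  allele frequencies under the Balding–Nichols model
  (f_breed ~ Beta(p(1−F)/F, (1−p)(1−F)/F), default F_ST = 0.2),
  Hardy–Weinberg genotypes with a planted associated locus, heavy-tailed
  two-channel intensities with chip batch effects, planted fixation / decoy
  / zero-heterozygosity regions, a 16-dog sequencing table with four genes
  carrying 10/16/12/16 case-only variants, and a 94-dog genotyping panel
  whose QC failures are planted.

## Worked example

```python
from breedmap import SimulationConfig, call_genotypes, concordance, qc_filter
from breedmap.simulate import simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=1))
calls = call_genotypes(ds.intensities).to_genotype_matrix()
print(concordance(calls, ds.truth_genotypes))
```

Running `python examples/02_call_genotypes.py` prints

```
concordance vs planted truth: 99.91% over 195,265 called genotypes (call rate 97.6%)
cohort QC kept 941 SNPs x 200 dogs; removed 59 items:
reason
maf    59
```

i.e. 99.91 % of confidently called genotypes match the simulated truth, and
the MAF > 5 % filter removes 59 near-monomorphic SNPs before association.
The burden stage (`python examples/06_caseonly_burden.py`) recovers the
planted per-gene counts exactly and reproduces the study-scale contrast:

```
per-dog constrained counts: case median 15.0 vs control 2.5 (exact rank-sum P = 0.00016)
...
panel contrast over 114 variants: median frequency 0.173 in risk breeds vs
0.028 in control breeds (signed-rank P = 1.9e-20); Pearson r (overall AF vs
normalized difference) = -0.58
```

Case dogs carry a median of 15 constrained case-only variants against 2.5
control-only variants per control dog; the case-only variants are common in
risk breeds (median frequency ≈ 0.17) but rare in control breeds and rare
overall, giving the negative frequency–contrast correlation. The remaining
`examples/` scripts walk through association + clumping, the selection
scans, and the permutation enrichment.

A `breedmap` console command mirrors the stages
(`simulate`, `callgeno`, `assoc`, `clump`, `scan`, `enrich`, `burden`,
`contrast`); every input and output is plain TSV/VCF/BED/GMT text.

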