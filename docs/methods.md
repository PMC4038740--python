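# Methods

This note records the models, parameter choices and numerical decisions
behind `breedmap`, and what the synthetic benchmarks do and do not show.

## Synthetic study model

The generator (`breedmap.simulate`) produces every input the pipeline
consumes, from one `SimulationConfig`, with all randomness derived from a
single seed (per-stage independent streams; identical config ⇒
byte-identical files).

**Breed structure.** Per-SNP ancestral frequencies are uniform on
[0.05, 0.95]; each breed draws its frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F), the Balding–Nichols model, so breed
frequencies have mean p and variance F·p(1−p). The default F_ST = 0.2
reflects the strong differentiation of dog breeds; it is a single,
analytically checkable parameter (the test suite verifies the variance
law by Monte Carlo). The default study genotypes 4 breeds × 50 dogs at
1,000 SNPs on one 100 Mb chromosome; multi-chromosome studies are
emulated by repeated independent blocks.

**Planted features.** One associated locus (case AF 0.6 vs control 0.2
across breeds, within-breed Hardy–Weinberg draws elsewhere); a 1.5 Mb
fixation region and a 0.9 Mb *decoy* (same near-fixed frequencies, but
below the 1 Mb span rule) in the first breed, each seeded with a fixed
block of SNPs so the criteria are decidable on every draw — the decoy is
ringed by guard SNPs held at frequency 0.35 so no qualifying interval can
stretch across it; a zero-heterozygosity 150 kb window at the chromosome
start (see *Tie-breaking*, below); four genes carrying 10/16/12/16
case-only and 2/2/3/3 control-only variants in gene ± 5 kb, with 80 % of
the planted variants inside constrained elements; and a genotyping panel
of 94 dogs × 127 variants in which exactly 6 dogs and 13 variants are
loaded with extra missingness so the printed QC thresholds reproduce the
88-dog × 114-variant working set (individual seeds can shed one further
dog through binomial tail luck, as real panels do).

**Intensities.** Each (sample, SNP) point is the cluster mean of its true
genotype — (2.0, 0.2), (1.1, 1.1), (0.2, 2.0) in (A, B) channel space —
plus independent-axis t-distributed noise with ν = 5 (heavy tails are what
make real array data hard), scaled by the sample's chip factor
(default chips ×1.0 and ×1.3). The default noise scale 0.13 puts the
minimal between-cluster distance at ~10× the scale, which reproduces the
per-SNP call rates (>90 %) and ~99.5 % concordance regime of real arrays;
a 6×-separation stress setting (scale 0.212) is used by the acceptance
checks of the caller. At exactly 6× with ν = 5, the Bayes error of any
forced-call classifier is ≈2 % (t₅ tail mass beyond half the separation),
so high concordance there is achievable only through abstention — which is
how array callers behave, and why concordance is defined over non-missing
calls with the call rate reported alongside.

**What the generator does not emulate.** Linkage disequilibrium decay
(SNPs are exchangeable given breed frequencies; LD in tests is built
directly where needed), pedigree structure, genotyping error correlated
with probe sequence, and read-level sequencing artefacts. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to every failure mode of real array or
sequence data.

## Genotype caller

The caller follows the intensity-clustering approach: no prior cluster
positions and no Hardy–Weinberg assumption.

1. **Normalization.** Within each chip, every sample's pooled A+B vector is
   replaced by the rank-matched mean of the chip's sorted vectors (ties get
   the interpolated value, so within-sample rank order is preserved
   exactly). Chip profiles are then averaged on a unit-mean scale and every
   sample is rank-matched into that grand profile. The second step is the
   identity for a single chip; for multiple chips it is what actually
   removes chip-level batch factors — per-chip normalization alone leaves
   each chip on its own scale and visibly splits every genotype cluster
   into per-chip subclusters. A multiplicative chip factor provably cancels
   (profiles are compared on a unit-mean scale), which the test suite
   asserts by comparing call matrices under chip factors {1, 1} and
   {2.0, 0.5}.
2. **Per-SNP PCA.** Each SNP's (A, B) cloud is centred and rotated to its
   principal axes; PC1 is oriented along increasing A. Clustering uses both
   components: PC2 carries the off-axis scatter that separates overlapping
   clusters when noise is anisotropic after normalization.
3. **EM t-mixture.** A k = 3 component bivariate t mixture with fixed
   ν = 5 (location, scale matrix and weight per component) is fitted by EM.
   Initialization is the globally optimal 1-D k-means split of PC1
   (O(k·n²) dynamic programming) — equal-quantile splits reliably trap EM
   in local optima at skewed allele frequencies. Convergence is declared
   when the log-likelihood changes by less than 10⁻⁶ per sample (an
   absolute-per-point criterion, invariant to global rescaling of the
   data, unlike a relative one — the log-likelihood shifts additively
   under rescaling); maximum 200 iterations; an emptied component triggers
   one jittered re-initialization, after which the SNP is flagged. A small
   ridge (10⁻⁸ of the data variance) keeps scale matrices positive
   definite. The log-likelihood is non-decreasing across iterations
   (asserted to 10⁻⁸ relative on every fixture).
4. **Component → dosage mapping.** Each fitted component is assigned the
   genotype implied by its back-projected allele contrast
   (A−B)/(|A|+|B|): above +1/3 → hom-ref (0), below −1/3 → hom-alt (2),
   else het (1); components landing in the same bucket pool their
   posteriors. Rank-ordering components along PC1 — the obvious
   alternative — misassigns dosages whenever a genotype class is absent
   (near-monomorphic SNPs: two of the three components then split one
   cluster), which is why the contrast anchoring exists; PC1 ordering
   remains the fallback when no back-projection is available. Measured on
   simulated data, the contrast bucket of a component is wrong only for
   genuinely mixed components (3 of ~1,200).
5. **Calls and QC.** Call = argmax pooled posterior if it reaches 0.95,
   else missing; SNPs whose resulting call rate falls below 50 % are
   flagged. Cohort QC removes, in this order: SNPs with call rate ≤ 0.90,
   samples with call rate ≤ 0.25 (recomputed), SNPs with MAF ≤ 0.05
   (recomputed) — the PLINK convention; the order is pinned by a fixture
   on which swapping the first two steps changes the output.

## Association, LD and clumping

The allelic test is the 1-df chi-squared n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))
on the 2×2 allele-count table, without continuity correction, dropping
missing genotypes per SNP; monomorphic SNPs report statistic 0, P = 1,
flagged. The chi-squared reference distribution is asymptotic: its null
P-values are uniform to KS < 0.02 only once a few thousand alleles enter
each table, so the calibration check simulates 800 cases and 800 controls;
at two-figure cohort sizes the discreteness of the table alone produces
KS ≈ 0.05 against the continuous uniform.

LD is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (deterministic, no haplotype phasing; fewer than
3 complete pairs or a degenerate vector → r² = 0, flagged). Clumping is
greedy: the unassigned SNP with smallest P (< 10⁻⁴; ties by position)
seeds a clump and absorbs unassigned SNPs within 1 Mb (index-to-SNP,
inclusive) with r² > 0.8 and P < 0.01; a region spans its members'
positions. Membership is disjoint by construction and re-validated after
every run; region *spans* may overlap (an unabsorbed index inside another
clump's span), as with PLINK. Correctness is pinned by an exhaustive
restatement of the rule on ≤50-SNP instances, not by the implementation's
own logic. Region-to-gene expansion takes genes overlapping
[start − 500 kb, end + 500 kb), half-open.

## Selection scans

**Fixation regions** are all maximal runs of consecutive SNPs spanning
more than 1 Mb, containing more than five SNPs, with strictly more than
95 % of them at MAF < 0.05. Maximality means neither adjacent SNP can be
absorbed without breaking a criterion; maximal intervals can overlap, and
each reported interval individually satisfies the criteria (re-checked
post hoc by an independent validator). The scan is an O(n²) prefix-sum
enumeration pinned against a literal brute force; SNP input order is
irrelevant (sorting is internal).

**RRVs.** The genome is tiled in non-overlapping 150 kb windows; a
window's variability is the mean expected heterozygosity 2p(1−p) over its
SNPs; the target breed's score is divided by the mean reference-breed
score plus ε = 10⁻⁶ (so reference-fixed windows do not blow up); exactly
⌊0.01 × W⌋ of the W retained windows (those with SNPs in target and
references) are reported, adjacent selected windows merged in the region
output but counted pre-merge. An absolute mode (no reference
normalization) is available. *Tie-breaking:* scores tie exactly at 0
whenever a window is monomorphic in the sample — windows inside fixation
regions do this routinely — so ties resolve deterministically to the
earliest window; the generator plants its zero-heterozygosity window at
the chromosome start so that its recovery exercises this documented rule
rather than seed luck. In the full pipeline the scans run on
call-rate-filtered calls *without* the MAF filter, which would delete
exactly the near-monomorphic SNPs the fixation criterion needs; note that
~0.1 % caller error is enough to lift a truly-zero window's estimated
heterozygosity above windows that are zero by sampling accident, so
window-exact RRV recovery is a property of the scan on genotypes, not of
the called pipeline.

**Cross-breed differential scoring.** Sets with target enrichment
P < 0.05 and ≥ 2 target RRV genes are scored by the mean over reference
breeds of (P_ref − P_target); sets whose target P undercuts every
reference are flagged breed-specific. Under exchangeability the flag rate
for a null set is 1/(n_ref + 1), verified by simulation.

## Permutation enrichment

Per set, the observed statistic is the number of candidate regions
containing at least one set gene (a region counts once however many genes
it holds). The null relocates each region uniformly on the genome
(chromosome chosen proportional to placeable length), keeping its length
and matching its overlapped-gene count within ±1, from a pre-sampled pool
of up to 400 accepted placements per region (unmatched fallback if
matching is impossible). This preserves the confounders that break naive
tests — region size, gene size and density, gene count — in the spirit of
interval-based enrichment tools, without reproducing any specific tool's
matching scheme. Sets are first filtered to 5–1,000 mapped genes.

Empirical P is the add-one estimator (1 + #{null ≥ obs})/(1 + n_perm), so
it is never 0 and never below 1/(n_perm + 1); corrected P comes from a
min-P second level over the same null draws (for each replicate, each
set's null value is converted to its own empirical P; corrected P of a set
counts replicates whose minimum is at least as extreme), which guarantees
corrected ≥ empirical; the count of sets with empirical P < 0.01 gets a
meta-P by the same device. Defaults: n_perm = 10,000 (larger values are
config-reachable).

Because the statistic is a small integer (0 … #regions), the reported
add-one P is conservative by construction — its null median sits near 0.7
at ten regions, as for any discrete permutation P — and P-values of sets
sharing one region set are mutually dependent. Calibration of the
permutation null itself is therefore verified through the randomized PIT
(uniform for any discrete statistic when the null is correctly specified),
computed from the exposed tie counts over independent replicates; the
reported estimator stays the conservative one.

## Case-only burden and contrasts

A variant is **case-only** if its alternate allele is carried by at least
one case, by no control, *and* genotypes are non-missing in at least a
configurable fraction of controls (default 1.0 — absence must be
observed, not assumed; exclusive variants failing it are
"private-missing"); control-only is symmetric; everything else is
"shared". Constrained-element membership is half-open interval
intersection (a variant at an element's end coordinate is outside).

Per-dog comparisons count, for each case dog, the case-only variants it
carries (optionally restricted to constrained elements, optionally
excluding coding consequences) against control dogs' control-only counts,
with named dogs excludable (e.g. a pair with poor genotyping accuracy);
the two-sided Wilcoxon rank-sum is exact for group sizes ≤ 10 (the
sequencing panel's regime) and tie-corrected normal above. Gene burden
counts exclusive variants in gene ± 5 kb, overall and constrained-only,
and ranks genes by the pseudocounted constrained ratio
(case + 1)/(control + 1) — the pseudocount lets zero-control genes rank
while raw counts are always reported so the unmodified ratio is
recoverable. No multiple-testing correction is applied to per-gene burden
(descriptive use); leave-breed-out reclassifies and recomputes after
dropping one breed's dogs. Candidate selection for follow-up genotyping
applies the six design criteria, restricting the case-only criteria
(target breed, focus genes, ≥ 2 breeds) to constrained elements.

Panel QC removes samples with missingness > 10 % and then variants with
call rate < 90 %. The frequency contrast reports per-group medians, a
two-sided signed-rank test on the per-variant paired frequencies (the
pairing is per variant across breed groups; all-zero differences give
P = 1), and the Pearson correlation between overall allele frequency and
the normalized difference (a − b)/(a + b) — exactly antisymmetric, bounded
in [−1, 1], undefined (excluded, flagged) when both frequencies are 0.

## Problem sizes

The shipped benchmarks run the caller at 1,000 SNPs × 200 samples, the
clumping and fixation oracles at ≤ 50 and ≤ 200 SNPs over hundreds of
random instances, enrichment power at 10,000 permutations over 20 seeds
with null calibration over 1,000 independent replicates, and burden
recovery over 100 seeds; the full pipeline runs in well under a minute on
one core. The study-scale knobs (25-breed reference panels, 10⁶
permutations) are reachable through the same configs.

## Known limitations

- The caller assumes a diploid autosomal model with three clusters; CNVs,
  X-linked dosage and chip-specific probe effects are out of scope.
- r² on dosages slightly underestimates haplotype r² when phase matters;
  clumping inherits that approximation.
- The enrichment null matches gene count within ±1 and region length
  exactly but does not stratify by SNP density (the synthetic SNP map is
  exchangeable, so density matching would be vacuous here).
- With a single sequenced dog pair per breed, leave-breed-out burden is
  noisy; it is reported, not tested, at that scale.
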