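"""Case/control association, LD clumping and gene mapping.

Runs the 1-df allelic chi-squared on QC-filtered calls, groups significant
SNPs (P < 1e-4) into regions by distance (1 Mb) and LD (r^2 > 0.8), and
expands each region by 500 kb to list candidate genes.
"""

import numpy as np

from breedmap import (SimulationConfig, allelic_chisq, call_genotypes, clump,
                      expand_regions, qc_filter)
from breedmap.simulate import simulate_dataset

config = SimulationConfig(seed=1)
ds = simulate_dataset(config)
calls, _ = qc_filter(call_genotypes(ds.intensities).to_genotype_matrix())

assoc = allelic_chisq(calls)
top = assoc.nsmallest(3, "p")[["id", "pos", "chi2", "p"]]
print("top association signals:")
print(top.to_string(index=False))

regions = clump(assoc, calls)
print(f"\n{len(regions)} clumped region(s):")
for _, r in regions.regions.iterrows():
    print(f"  {r['label']}: {r['chrom']}:{r['start']:,}-{r['end']:,} "
          f"(index P = {r['score']:.2e}, "
          f"{len(regions.members[r['label']])} SNPs)")

genes = expand_regions(regions, ds.catalog)
for label, gl in genes.items():
    print(f"  {label} +/-500 kb covers genes: {', '.join(gl) or '(none)'}")

planted = config.planted_assoc[0][0]
hit = any(r["start"] <= planted < r["end"]
          for _, r in regions.regions.iterrows())
print(f"\nplanted locus at {planted:,} bp inside a clump: {hit}")
# The planted 0.6-vs-0.2 allele-frequency contrast produces a chi-squared
# around 70-90 (P ~ 1e-17), and the clump around it is the top region.
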