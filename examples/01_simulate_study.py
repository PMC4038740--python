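"""Generate a synthetic breed-structured mapping study and look inside.

Builds the default study: 4 breeds x 50 dogs genotyped on 1,000 SNPs under
Balding-Nichols differentiation (F_ST = 0.2), with a planted associated
locus, a planted 1.5 Mb fixation region, a planted zero-heterozygosity
window, four genes loaded with case-only variants, and a 94-dog genotyping
panel.
"""

from breedmap import SimulationConfig, simulate_dataset

config = SimulationConfig(seed=1)
ds = simulate_dataset(config)

print(f"genotypes: {ds.truth_genotypes.n_samples} dogs x "
      f"{ds.truth_genotypes.n_snps} SNPs from breeds "
      f"{sorted(set(ds.truth_genotypes.samples['breed']))}")
print(f"intensities: {ds.intensities.values.shape} (sample, SNP, channel)")
print(f"gene catalog: {len(ds.catalog)} genes; "
      f"{len(ds.sets)} gene sets; {len(ds.constrained)} constrained elements")
print(f"sequencing table: {len(ds.variant_table)} variants over "
      f"{len(ds.seq_dogs)} dogs ({(ds.seq_dogs['group'] == 'case').sum()} cases)")
print(f"genotyping panel: {ds.panel.genotypes.shape[0]} dogs x "
      f"{ds.panel.genotypes.shape[1]} variants")
print("\nplanted truth:")
print(f"  associated locus at {config.planted_assoc[0][0]:,} bp "
      f"(case AF {config.planted_assoc[0][1]}, control {config.planted_assoc[0][2]})")
print(f"  fixed region {config.planted_fixed_region[0]:,}-"
      f"{config.planted_fixed_region[1]:,} bp")
print(f"  burden genes: "
      + ", ".join(f"{g} ({c} case-only)" for g, c, _ in config.planted_burden_genes))
# The printed shapes are the inputs every later stage consumes; the planted
# truth is what the pipeline must recover.
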