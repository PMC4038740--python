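import numpy as np
import pandas as pd
import pytest

from breedmap.containers import GenotypeMatrix
from breedmap.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(default_config):
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def callset(dataset):
    from breedmap import caller as cl
    return cl.call_genotypes(dataset.intensities)


def make_genotype_matrix(geno, positions=None, groups=None, breeds=None,
                         chrom="chr1"):
    """GenotypeMatrix from a raw (n_samples, n_snps) array; test helper."""
    geno = np.asarray(geno, dtype=np.int8)
    n_s, n_p = geno.shape
    positions = np.arange(n_p) * 1000 if positions is None else positions
    samples = pd.DataFrame({
        "sample": [f"s{i}" for i in range(n_s)],
        "breed": ["b1"] * n_s if breeds is None else list(breeds),
        "group": (["case"] * (n_s // 2) + ["control"] * (n_s - n_s // 2)
                  if groups is None else list(groups)),
    })
    snps = pd.DataFrame({
        "id": [f"v{j}" for j in range(n_p)],
        "chrom": chrom, "pos": np.asarray(positions, dtype=int),
        "ref": "A", "alt": "B",
    })
    return GenotypeMatrix(geno, snps, samples)
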