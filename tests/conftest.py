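import numpy as np
import pandas as pd
import pytest

from popsweep.genotype_io import GenotypeDataset, PopulationMap
from popsweep.synthetic_data import SimConfig, simulate_dataset


def build_dataset(calls, chrom="chr1", positions=None, chrom_lengths=None):
    """GenotypeDataset from a (n_samples, n_sites) array of 0/1/2/-1 codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"s{i}" for i in range(n_sites)],
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"ind{i:02d}" for i in range(n_samples)]
    return GenotypeDataset(variants, samples, calls, chrom_lengths)


def popmap_for(dataset, pop_sizes, groups=None):
    """PopulationMap assigning the first n1 samples to pop1, next n2 to pop2, ...

    ``pop_sizes`` maps population name -> size; ``groups`` maps population ->
    group (defaults to one group 'G').
    """
    sample_population = {}
    it = iter(dataset.samples)
    for pop, n in pop_sizes.items():
        for _ in range(n):
            sample_population[next(it)] = pop
    population_group = {p: (groups or {}).get(p, "G") for p in pop_sizes}
    return PopulationMap(sample_population, population_group)


@pytest.fixture(scope="session")
def sim_two_group():
    """Small two-group, three-population simulated dataset with truth."""
    cfg = SimConfig(
        groups=[("north", [("P1", 10), ("P2", 8)]), ("south", [("P3", 10)])],
        n_chromosomes=2,
        chrom_length=200_000,
        n_snps_per_chrom=300,
        f_ct=0.05,
        f_sc=0.03,
        missing_rate=0.03,
        seed=42,
    )
    return simulate_dataset(cfg)
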