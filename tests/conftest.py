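import numpy as np
import pytest

from pinpop.genotypes import GenotypeMatrix
from pinpop.simulate import SimulationConfig, generate_dataset


def make_gm(genotypes, pop_labels=None, region_labels=None, depths=None,
            pos=None):
    """Build a GenotypeMatrix from a (n_ind, n_sites) dosage array; depth
    defaults to 30 reads split by genotype (hets 15/15)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_sites = g.shape
    if depths is None:
        depths = np.zeros((n_ind, n_sites, 2), dtype=np.int32)
        depths[..., 0] = np.where(g == 0, 30, np.where(g == 1, 15, 0))
        depths[..., 1] = np.where(g == 2, 30, np.where(g == 1, 15, 0))
        depths[g == -1] = 0
    if pop_labels is None:
        half = n_ind // 2
        pop_labels = ["p1"] * half + ["p2"] * (n_ind - half)
    if region_labels is None:
        pops = list(dict.fromkeys(pop_labels))
        mid = (len(pops) + 1) // 2
        region_of = {p: ("SMO" if i < mid else "ChD")
                     for i, p in enumerate(pops)}
        region_labels = [region_of[p] for p in pop_labels]
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    chrom = np.array(["ctg1"] * n_sites, dtype=object)
    return GenotypeMatrix(g, np.asarray(depths, dtype=np.int32), chrom,
                          np.asarray(pos), list(pop_labels),
                          list(region_labels))


@pytest.fixture(scope="session")
def small_dataset():
    """A small default-model synthetic dataset shared across tests."""
    return generate_dataset(SimulationConfig(n_snps=400, seed=20240917))
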