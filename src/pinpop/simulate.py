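"""GBS-like synthetic genotype datasets with known generating truth.

Clean sites are unlinked coalescent draws from a two-deme demographic
model, conditioned on segregating in the pooled sample; read depths are
Poisson around a mean per-site coverage with heterozygote allele splits
Binomial(depth, 1/2); missing genotypes are inserted uniformly at random.

A configurable fraction of *artifact* loci emulates the collapsed-paralog
signal that motivates HDplot filtering in conifer GBS data: two
independent loci are merged into one apparent locus, so the apparent
genotype is derived from four chromosomes and heterozygote read ratios
are drawn off 1:2:1. By default half of the artifact loci carry a fixed
difference in the duplicate copy (the strongest and commonest real-data
signature: nearly every individual appears heterozygous with alternate-
biased reads); the rest merge two segregating loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .demography import DemographicModel, sample_genotypes
from .genotypes import GenotypeMatrix, write_vcf as _write_vcf
from .published import best_fit_model

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_dataset",
           "write_vcf", "write_truth_sidecar", "read_truth_sidecar"]


@dataclass
class SimulationConfig:
    n_pops_per_region: tuple[int, int] = (5, 5)
    n_ind_per_pop: int = 9
    n_snps: int = 3100
    model: DemographicModel = field(default_factory=best_fit_model)
    missing_rate: float = 0.09
    mean_depth: float = 64.0
    paralog_fraction: float = 0.05
    fixed_difference_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pops_per_region) < 1 or self.n_ind_per_pop < 1:
            raise ValueError("population counts must be >= 1")
        if sum(self.n_pops_per_region) < 2:
            raise ValueError("need at least two populations")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("missing_rate", "paralog_fraction",
                     "fixed_difference_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    truth: DemographicModel
    paralog_site_ids: list[str]
    implied_total_length: float


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one dataset; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    n_art = int(round(config.paralog_fraction * config.n_snps))
    n_clean = config.n_snps - n_art
    # extra simulated loci serve as second copies for merged artifacts
    n_sim = config.n_snps + n_art
    dosages, pop_labels, region_labels = sample_genotypes(
        config.model, config.n_pops_per_region, config.n_ind_per_pop,
        n_sim, seed=int(rng.integers(2 ** 31)))
    n_ind = dosages.shape[0]

    # choose artifact positions among the final site order
    art_pos = np.sort(rng.choice(config.n_snps, size=n_art, replace=False))
    is_artifact = np.zeros(config.n_snps, dtype=bool)
    is_artifact[art_pos] = True
    fixed_copy = rng.random(n_art) < config.fixed_difference_fraction

    genotypes = np.empty((n_ind, config.n_snps), dtype=np.int8)
    depths = np.zeros((n_ind, config.n_snps, 2), dtype=np.int32)
    next_primary = 0
    next_extra = config.n_snps  # simulated loci reserved for second copies
    art_i = 0
    for s in range(config.n_snps):
        g1 = dosages[:, next_primary]
        next_primary += 1
        if is_artifact[s]:
            if fixed_copy[art_i]:
                g2 = np.full(n_ind, 2, dtype=np.int8)
            else:
                g2 = dosages[:, next_extra]
                next_extra += 1
            art_i += 1
            merged = g1.astype(np.int32) + g2  # dosage over 4 chromosomes
            geno = np.where(merged == 0, 0, np.where(merged == 4, 2, 1))
            depth = rng.poisson(2 * config.mean_depth, size=n_ind)
            alt = rng.binomial(depth, merged / 4.0)
        else:
            geno = g1
            depth = rng.poisson(config.mean_depth, size=n_ind)
            alt = np.where(geno == 1, rng.binomial(depth, 0.5),
                           np.where(geno == 2, depth, 0))
        genotypes[:, s] = geno
        depths[:, s, 0] = depth - alt
        depths[:, s, 1] = alt

    # uniform missingness
    miss = rng.random((n_ind, config.n_snps)) < config.missing_rate
    genotypes[miss] = -1
    depths[miss] = 0

    chrom = np.array(["ctg1"] * config.n_snps, dtype=object)
    pos = np.arange(1, config.n_snps + 1, dtype=np.int64) * 500
    gm = GenotypeMatrix(genotypes, depths, chrom, pos, pop_labels,
                        region_labels)
    site_ids = gm.site_ids
    paralog_ids = [site_ids[s] for s in np.nonzero(is_artifact)[0]]
    # implied callable length for absolute-mode likelihoods: a clean site
    # panel of n_snps SNPs corresponds to n_snps/(mu * E[tree length]) bases
    from .demography import expected_branch_matrix
    n_a = 2 * config.n_pops_per_region[0] * config.n_ind_per_pop
    n_b = 2 * config.n_pops_per_region[1] * config.n_ind_per_pop
    mean_len = expected_branch_matrix(config.model, n_a, n_b, 500,
                                      (config.seed + 11) % (2 ** 31)).sum()
    implied_length = config.n_snps / (config.model.mu * mean_len)
    return SyntheticDataset(gm, config.model, paralog_ids, implied_length)


def drop_to_sample_shape(dataset: SyntheticDataset,
                         n_keep: int) -> SyntheticDataset:
    """Drop the highest-missingness individuals down to ``n_keep`` (the
    original study retained 88 of 90 sampled trees)."""
    gm = dataset.genotypes
    missing = (gm.genotypes == -1).mean(axis=1)
    keep = np.argsort(missing, kind="stable")[:n_keep]
    return replace(dataset, genotypes=gm.take_individuals(np.sort(keep)))


def write_vcf(dataset: SyntheticDataset, path) -> None:
    """Write the dataset as VCF 4.2 with GT and AD fields; sample names
    encode region and population and round-trip through the reader."""
    _write_vcf(dataset.genotypes, path)


def write_truth_sidecar(dataset: SyntheticDataset, path) -> None:
    """Tabular one-parameter-per-row record of the generating model."""
    m = dataset.truth
    with open(path, "w") as fh:
        fh.write("parameter\tvalue\n")
        fh.write(f"scenario\t{m.scenario}\n")
        for name in ("n_smo", "n_chd", "t_div", "m_smo_to_chd",
                     "m_chd_to_smo", "t_con_smo", "t_con_chd", "n_smo_pre",
                     "n_chd_pre", "n_anc", "mu", "gen_time"):
            v = getattr(m, name)
            if v is not None:
                fh.write(f"{name}\t{float(v)!r}\n")
        fh.write(f"implied_total_length\t{float(dataset.implied_total_length)!r}\n")
        for sid in dataset.paralog_site_ids:
            fh.write(f"paralog_site\t{sid}\n")


def read_truth_sidecar(path) -> tuple[DemographicModel, list[str], float]:
    fields: dict = {}
    paralogs: list[str] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            key, value = line.rstrip("\n").split("\t")
            if key == "paralog_site":
                paralogs.append(value)
            elif key == "scenario":
                fields[key] = value
            else:
                fields[key] = float(value)
    length = fields.pop("implied_total_length", 0.0)
    return DemographicModel(**fields), paralogs, length
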