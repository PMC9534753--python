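"""Two-deme demographic scenarios and their expected joint SFS.

The geography is modelled as two demes — SMO (Sierra Madre Oriental) and
ChD (Chihuahuan Desert) — that split from a single ancestral deme T_DIV
generations ago. Four scenarios are supported:

    DIV     divergence only (N_SMO, N_ChD, T_DIV)
    DIV_M   divergence plus asymmetric continuous migration
    CON     divergence followed by independent recent contractions of each
            deme (pre-contraction sizes N_*_pre, contraction times T_CON_*)
    CON_M   contraction scenario plus migration

Migration rates are specified in the forward-time direction of gene flow
(``m_SMO_to_ChD`` is the per-generation probability that a ChD individual
has an SMO parent); they are converted internally to the backward-in-time
per-lineage rates the coalescent uses (a lineage sampled in ChD traces to
SMO at rate m_SMO_to_ChD).

The ancestral deme size defaults to N_SMO + N_ChD at the merge (mass
conservation); set ``n_anc`` explicitly to override or to treat it as a
free parameter during fitting.

Expected joint site-frequency spectra are estimated by Monte-Carlo: the
mean branch-length matrix over replicate structured-coalescent genealogies
gives, scaled by the mutation rate, the per-site probability of each
derived-count configuration (infinite-sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._coalescent import (
    branch_length_matrix,
    sample_site_counts,
    sample_site_leafsets,
)
from .sfs import JointSFS

SCENARIOS = ("DIV", "DIV_M", "CON", "CON_M")

#: default per-generation, per-base mutation rate (Pinaceae estimate)
MU_PER_GENERATION = 2.91e-8
#: default generation time in years (long-lived pinyon pines)
GENERATION_TIME_YEARS = 40.0


def generations_to_years(g: float, gen_time: float = GENERATION_TIME_YEARS) -> float:
    """Convert a time in generations to years."""
    if gen_time <= 0:
        raise ValueError("generation time must be positive")
    return g * gen_time


def mu_per_year(mu_gen: float, gen_time: float = GENERATION_TIME_YEARS) -> float:
    """Convert a per-generation mutation rate to a per-year rate."""
    if gen_time <= 0:
        raise ValueError("generation time must be positive")
    return mu_gen / gen_time


@dataclass
class DemographicModel:
    """A fully parameterised two-deme scenario in absolute units.

    Sizes are diploid individuals, times are generations before present,
    migration rates are per-lineage per-generation probabilities in the
    forward gene-flow direction.
    """

    scenario: str
    n_smo: float
    n_chd: float
    t_div: float
    m_smo_to_chd: float = 0.0
    m_chd_to_smo: float = 0.0
    t_con_smo: Optional[float] = None
    t_con_chd: Optional[float] = None
    n_smo_pre: Optional[float] = None
    n_chd_pre: Optional[float] = None
    n_anc: Optional[float] = None
    mu: float = MU_PER_GENERATION
    gen_time: float = GENERATION_TIME_YEARS

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if min(self.n_smo, self.n_chd) <= 0 or self.t_div <= 0:
            raise ValueError("deme sizes and T_DIV must be positive")
        if self.mu <= 0 or self.gen_time <= 0:
            raise ValueError("mu and gen_time must be positive")
        if not (0 <= self.m_smo_to_chd < 1 and 0 <= self.m_chd_to_smo < 1):
            raise ValueError("migration rates must lie in [0, 1)")
        if self.scenario in ("CON", "CON_M"):
            for name in ("t_con_smo", "t_con_chd", "n_smo_pre", "n_chd_pre"):
                if getattr(self, name) is None:
                    raise ValueError(f"{name} required for scenario {self.scenario}")
            if not (0 < self.t_con_smo < self.t_div and 0 < self.t_con_chd < self.t_div):
                raise ValueError("contraction times must lie in (0, T_DIV)")
        if self.scenario in ("DIV", "CON") and (self.m_smo_to_chd or self.m_chd_to_smo):
            raise ValueError("migration rates must be zero in non-M scenarios")

    @property
    def ancestral_size(self) -> float:
        return self.n_anc if self.n_anc is not None else self.n_smo + self.n_chd

    @property
    def t_div_years(self) -> float:
        return generations_to_years(self.t_div, self.gen_time)

    def epochs(self):
        """Backward-time epoch arrays consumed by the coalescent kernels."""
        cuts = []
        if self.scenario in ("CON", "CON_M"):
            cuts = sorted({self.t_con_smo, self.t_con_chd})
        bounds = [c for c in cuts if c < self.t_div] + [self.t_div, math.inf]
        t_end = np.array(bounds)
        n0 = np.empty(len(bounds))
        n1 = np.empty(len(bounds))
        m0 = np.zeros(len(bounds))
        m1 = np.zeros(len(bounds))
        merged = np.zeros(len(bounds), dtype=np.int8)
        t_start = 0.0
        for e, te in enumerate(bounds):
            if te > self.t_div:  # ancestral epoch
                n0[e] = n1[e] = self.ancestral_size
                merged[e] = 1
            else:
                if self.scenario in ("CON", "CON_M"):
                    n0[e] = self.n_smo if t_start < self.t_con_smo else self.n_smo_pre
                    n1[e] = self.n_chd if t_start < self.t_con_chd else self.n_chd_pre
                else:
                    n0[e] = self.n_smo
                    n1[e] = self.n_chd
                # backward rates: lineage in ChD (deme 1) came from SMO at the
                # forward SMO->ChD rate, and vice versa
                m0[e] = self.m_chd_to_smo
                m1[e] = self.m_smo_to_chd
            t_start = te
        return t_end, n0, n1, m0, m1, merged

    def free_parameters(self, anc_free: bool = False) -> list[str]:
        """Names of the parameters estimated under this scenario."""
        names = ["n_smo", "n_chd", "t_div"]
        if self.scenario in ("CON", "CON_M"):
            names += ["n_smo_pre", "n_chd_pre", "t_con_smo", "t_con_chd"]
        if self.scenario in ("DIV_M", "CON_M"):
            names += ["m_smo_to_chd", "m_chd_to_smo"]
        if anc_free:
            names.append("n_anc")
        return names

    def with_params(self, **kwargs) -> "DemographicModel":
        return replace(self, **kwargs)


@dataclass
class SearchRanges:
    """Per-parameter (low, high, prior) search boxes for the optimiser.

    ``prior`` is "uniform" or "log_uniform" and also controls whether the
    coordinate search grids the parameter on a linear or log scale.
    """

    ranges: dict = field(default_factory=dict)

    @classmethod
    def default(cls, n_low=100.0, n_high=1000.0) -> "SearchRanges":
        return cls({
            "n_smo": (n_low, n_high, "uniform"),
            "n_chd": (n_low, n_high, "uniform"),
            "n_smo_pre": (n_low, n_high, "uniform"),
            "n_chd_pre": (n_low, n_high, "uniform"),
            "n_anc": (n_low, 2 * n_high, "uniform"),
            "t_div": (275.0, 62500.0, "uniform"),
            "t_con_smo": (40.0, 275.0, "uniform"),
            "t_con_chd": (40.0, 275.0, "uniform"),
            "m_smo_to_chd": (1e-9, 1e-4, "log_uniform"),
            "m_chd_to_smo": (1e-9, 1e-4, "log_uniform"),
        })

    def __post_init__(self):
        for name, (lo, hi, prior) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {name} must have low < high")
            if prior not in ("uniform", "log_uniform"):
                raise ValueError(f"unknown prior {prior!r} for {name}")

    def __getitem__(self, name):
        return self.ranges[name]

    def updated(self, **kwargs) -> "SearchRanges":
        new = dict(self.ranges)
        new.update(kwargs)
        return SearchRanges(new)

    def draw(self, names, rng) -> dict:
        out = {}
        for name in names:
            lo, hi, prior = self.ranges[name]
            if prior == "log_uniform":
                out[name] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            else:
                out[name] = rng.uniform(lo, hi)
        return out


def expected_branch_matrix(model: DemographicModel, n_a: int, n_b: int,
                           n_reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo mean branch-length matrix for samples of n_a + n_b
    chromosomes; entry (i, j) in generations."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 chromosomes per deme")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    t_end, n0, n1, m0, m1, merged = model.epochs()
    return branch_length_matrix(n_a, n_b, t_end, n0, n1, m0, m1, merged,
                                n_reps, seed % (2 ** 31))


def expected_sfs(model: DemographicModel, n_a: int, n_b: int, n_reps: int,
                 seed: int, mode: str = "conditional",
                 total_length: Optional[float] = None,
                 folded: bool = False) -> JointSFS:
    """Expected joint SFS under ``model`` for n_a + n_b sampled chromosomes.

    mode="conditional": proportions over segregating configurations.
    mode="absolute": per-site probabilities of each configuration given the
    model's mutation rate, with the residual monomorphic probability stored
    in the (0, 0) corner; ``total_length`` (callable bases) then scales the
    spectrum to expected site *counts* if provided.
    """
    if mode not in ("conditional", "absolute"):
        raise ValueError("mode must be 'conditional' or 'absolute'")
    M = expected_branch_matrix(model, n_a, n_b, n_reps, seed)
    M[0, 0] = 0.0
    M[n_a, n_b] = 0.0
    if mode == "conditional":
        counts = M / M.sum()
    else:
        counts = M * model.mu
        p_seg = counts.sum()
        if p_seg >= 1.0:
            raise ValueError("mu * tree length >= 1; absolute mode invalid")
        counts[0, 0] = 1.0 - p_seg
        if total_length is not None:
            counts = counts * total_length
    out = JointSFS(counts=counts, folded=False)
    out.n_reps = n_reps
    if folded:
        out = out.fold()
        out.n_reps = n_reps
    return out


def simulate_sfs_counts(model: DemographicModel, n_a: int, n_b: int,
                        n_snps: int, seed: int,
                        folded: bool = True) -> tuple[JointSFS, float]:
    """Simulate the joint SFS of ``n_snps`` unlinked segregating SNPs.

    Sites are drawn conditional on segregating in the pooled sample, with
    the genealogy length-biased as required by that conditioning. Returns
    (sfs, implied_total_length): the number of callable bases that would,
    in expectation, yield ``n_snps`` segregating sites under the model
    (n_snps / (mu * mean tree length)).
    """
    if n_snps < 0:
        raise ValueError("n_snps must be non-negative")
    t_end, n0, n1, m0, m1, merged = model.epochs()
    # pilot run to set the rejection envelope
    pilot = branch_length_matrix(n_a, n_b, t_end, n0, n1, m0, m1, merged,
                                 200, (seed + 7) % (2 ** 31))
    t_cap = 6.0 * pilot.sum()
    ia, ib, mean_len, max_len = sample_site_counts(
        n_a, n_b, t_end, n0, n1, m0, m1, merged, n_snps, t_cap,
        seed % (2 ** 31))
    counts = np.zeros((n_a + 1, n_b + 1))
    np.add.at(counts, (ia, ib), 1.0)
    sfs = JointSFS(counts=counts, folded=False)
    if folded:
        sfs = sfs.fold()
    implied_length = n_snps / (model.mu * mean_len) if n_snps else 0.0
    return sfs, implied_length


def sample_genotypes(model: DemographicModel, pops_per_region: tuple[int, int],
                     ind_per_pop: int, n_snps: int, seed: int):
    """Simulate unlinked biallelic diploid genotypes under ``model``.

    Chromosomes are simulated per deme and paired at random into diploids;
    individuals within a region are split evenly over its populations
    (populations within a region are exchangeable samples of one deme).

    Returns (genotypes, pop_labels, region_labels) with genotypes an
    (n_individuals, n_snps) int8 array of alternate-allele dosages; the
    mutated (derived) allele is reported as the alternate allele.
    """
    from .genotypes import REGION_A, REGION_B

    p_a, p_b = pops_per_region
    ind_a = p_a * ind_per_pop
    ind_b = p_b * ind_per_pop
    n_a, n_b = 2 * ind_a, 2 * ind_b
    pop_labels = [f"SMO{i + 1}" for i in range(p_a) for _ in range(ind_per_pop)]
    pop_labels += [f"ChD{i + 1}" for i in range(p_b) for _ in range(ind_per_pop)]
    region_labels = [REGION_A] * ind_a + [REGION_B] * ind_b
    if n_snps == 0:
        return (np.zeros((ind_a + ind_b, 0), dtype=np.int8), pop_labels,
                region_labels)
    t_end, n0, n1, m0, m1, merged = model.epochs()
    pilot = branch_length_matrix(n_a, n_b, t_end, n0, n1, m0, m1, merged,
                                 200, (seed + 7) % (2 ** 31))
    t_cap = 6.0 * pilot.sum()
    carriers = sample_site_leafsets(n_a, n_b, t_end, n0, n1, m0, m1, merged,
                                    n_snps, t_cap, seed % (2 ** 31))
    # random pairing of chromosomes into diploids, independently per site is
    # wrong (sites share individuals); pair once per deme
    rng = np.random.default_rng(seed)
    perm_a = rng.permutation(n_a)
    perm_b = n_a + rng.permutation(n_b)
    order = np.concatenate([perm_a, perm_b])
    chrom = carriers[:, order].astype(np.int8)  # (n_snps, n_chrom)
    geno = chrom[:, 0::2] + chrom[:, 1::2]  # (n_snps, n_ind)
    return geno.T.copy(), pop_labels, region_labels
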