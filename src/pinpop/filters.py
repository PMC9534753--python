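"""Post-calling SNP curation cascade for GBS genotype data.

The cascade mirrors standard reduced-representation practice for conifer
data, where paralogs and pseudogenes are abundant: keep biallelic
segregating sites, mask low-depth genotypes and drop high-missingness
sites/individuals, remove putative paralogs with HDplot (per-site
heterozygote proportion H and standardized heterozygote read-ratio
deviation D), prune linked sites in sliding windows, and drop sites out of
Hardy-Weinberg equilibrium. Every stage appends to a FilterLedger so the
attrition of sites and individuals is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FilterConfig", "FilterLedger", "filter_biallelic",
    "filter_missingness_depth", "hdplot_H", "hdplot_D", "filter_hdplot",
    "ld_r2", "ld_prune", "hwe_exact_test", "filter_hwe", "run_cascade",
]


@dataclass
class FilterConfig:
    max_site_missing: float = 0.25
    max_ind_missing: float = 0.2
    min_depth: int = 15
    hdplot_max_h: float = 0.6
    hdplot_d_range: tuple[float, float] = (-10.0, 10.0)
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.5
    ld_window_unit: str = "variants"  # "variants" or "bp"
    hwe_alpha: float = 0.05
    hwe_scope: str = "per_pop"        # "per_pop" or "pooled"

    def __post_init__(self):
        for name in ("max_site_missing", "max_ind_missing", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.hdplot_max_h <= 1:
            raise ValueError("hdplot_max_h must lie in [0, 1]")
        if self.hdplot_d_range[0] >= self.hdplot_d_range[1]:
            raise ValueError("hdplot_d_range must be (low, high)")
        if self.min_depth < 0 or self.ld_window < 1 or self.ld_step < 1:
            raise ValueError("min_depth, ld_window, ld_step out of range")
        if not 0 <= self.ld_r2_max <= 1:
            raise ValueError("ld_r2_max must lie in [0, 1]")
        if self.ld_window_unit not in ("variants", "bp"):
            raise ValueError("ld_window_unit must be 'variants' or 'bp'")
        if self.hwe_scope not in ("per_pop", "pooled"):
            raise ValueError("hwe_scope must be 'per_pop' or 'pooled'")


@dataclass
class FilterLedger:
    stages: list = field(default_factory=list)

    def record(self, name: str, sites_in: int, sites_out: int,
               ind_in: int, ind_out: int) -> None:
        if sites_out > sites_in or ind_out > ind_in:
            raise ValueError("ledger counts must be non-increasing")
        self.stages.append((name, sites_in, sites_out, ind_in, ind_out))

    def extend(self, other: "FilterLedger") -> None:
        for stage in other.stages:
            self.record(*stage)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tsites_in\tsites_out\tindividuals_in\tindividuals_out\n")
            for row in self.stages:
                fh.write("\t".join(str(x) for x in row) + "\n")


def filter_biallelic(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep sites where both alleles are observed among called genotypes.

    Drops sites monomorphic in the sample, including sites fixed for the
    alternate allele (differences from the reference genome that do not
    segregate in the species).
    """
    called = gm.called()
    g = gm.genotypes
    has_ref = ((g == 0) | (g == 1)).any(axis=0)
    has_alt = ((g == 2) | (g == 1)).any(axis=0) & called.any(axis=0)
    return gm.take_sites(np.nonzero(has_ref & has_alt)[0])


def filter_missingness_depth(gm: GenotypeMatrix, cfg: FilterConfig
                             ) -> tuple[GenotypeMatrix, FilterLedger]:
    """Mask genotypes below the depth floor, then drop high-missingness
    sites, then high-missingness individuals; ledger records each stage."""
    ledger = FilterLedger()
    n_s, n_i = gm.n_sites, gm.n_individuals
    depth = gm.allele_depths.sum(axis=2)
    low = (depth < cfg.min_depth) & gm.called()
    genotypes = gm.genotypes.copy()
    genotypes[low] = MISSING
    gm = GenotypeMatrix(genotypes, gm.allele_depths, gm.chrom, gm.pos,
                        gm.pop_labels, gm.region_labels, gm.sample_names)
    ledger.record("min_depth", n_s, gm.n_sites, n_i, gm.n_individuals)

    site_missing = (gm.genotypes == MISSING).mean(axis=0)
    gm = gm.take_sites(np.nonzero(site_missing <= cfg.max_site_missing)[0])
    ledger.record("site_missingness", n_s, gm.n_sites, n_i, gm.n_individuals)

    n_s2 = gm.n_sites
    if n_s2:
        ind_missing = (gm.genotypes == MISSING).mean(axis=1)
        gm = gm.take_individuals(np.nonzero(ind_missing < cfg.max_ind_missing)[0])
    ledger.record("individual_missingness", n_s2, gm.n_sites, n_i,
                  gm.n_individuals)
    return gm, ledger


def hdplot_H(gm: GenotypeMatrix, site: int) -> float:
    """Proportion of called individuals heterozygous at a site."""
    g = gm.genotypes[:, site]
    called = g != MISSING
    if not called.any():
        raise ValueError("H undefined at an all-missing site")
    return float((g[called] == 1).mean())


def hdplot_D(gm: GenotypeMatrix, site: int) -> float:
    """Standardized deviation of pooled heterozygote reads from 1:1.

    With A (B) the summed reference (alternate) read counts over
    heterozygous genotypes, D = (A - B) / sqrt(A + B): approximately
    standard normal for a true single-copy site, far from 0 for merged
    paralogs whose copies contribute unequal read ratios.
    """
    het = gm.genotypes[:, site] == 1
    a = int(gm.allele_depths[het, site, 0].sum())
    b = int(gm.allele_depths[het, site, 1].sum())
    if a + b == 0:
        raise ValueError("D undefined without heterozygote reads")
    return (a - b) / math.sqrt(a + b)


def filter_hdplot(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Remove putative paralogs: H above the threshold or D outside the
    allowed band. Boundary values are retained (strict inequalities).
    Sites with no heterozygote reads have no read-ratio evidence and are
    judged on H alone."""
    lo, hi = cfg.hdplot_d_range
    keep = []
    for s in range(gm.n_sites):
        h = hdplot_H(gm, s)
        if h > cfg.hdplot_max_h:
            continue
        try:
            d = hdplot_D(gm, s)
        except ValueError:
            keep.append(s)
            continue
        if lo <= d <= hi:
            keep.append(s)
    return gm.take_sites(keep)


def ld_r2(gm: GenotypeMatrix, site_a: int, site_b: int) -> float:
    """Squared genotype-dosage correlation over jointly called individuals."""
    ga = gm.genotypes[:, site_a].astype(float)
    gb = gm.genotypes[:, site_b].astype(float)
    both = (gm.genotypes[:, site_a] != MISSING) & (gm.genotypes[:, site_b] != MISSING)
    ga, gb = ga[both], gb[both]
    if len(ga) < 2 or ga.std() == 0 or gb.std() == 0:
        raise ValueError("r2 undefined for monomorphic or empty overlap")
    r = np.corrcoef(ga, gb)[0, 1]
    return float(r * r)


def _pair_r2_or_zero(gm, a, b):
    try:
        return ld_r2(gm, a, b)
    except ValueError:
        return 0.0


def ld_prune(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Greedy windowed LD pruning.

    Within each sliding window (``ld_window`` consecutive variants, or a
    base-pair span when ld_window_unit='bp'), while any retained pair has
    r^2 >= ld_r2_max the member with greater missingness (ties: the later
    position) is removed; windows advance by ``ld_step``. Windows never
    span contigs. Because removals shift subsequent windows, the sweep is
    repeated until no site is removed, so the operation is idempotent.
    """
    order = np.lexsort((gm.pos, gm.chrom.astype(str)))
    gm = gm.take_sites(order)
    while True:
        missing = (gm.genotypes == MISSING).mean(axis=0)
        removed = np.zeros(gm.n_sites, dtype=bool)
        chroms = gm.chrom.astype(str)
        for contig in dict.fromkeys(chroms.tolist()):
            idx = np.nonzero(chroms == contig)[0]
            for window in _windows(gm.pos[idx], cfg):
                w = idx[window]
                _prune_window(gm, w, removed, missing, cfg.ld_r2_max)
        if not removed.any():
            return gm
        gm = gm.take_sites(np.nonzero(~removed)[0])


def _windows(pos, cfg):
    n = len(pos)
    if cfg.ld_window_unit == "variants":
        start = 0
        while start < n:
            yield np.arange(start, min(start + cfg.ld_window, n))
            if start + cfg.ld_window >= n:
                break
            start += cfg.ld_step
    else:
        start = 0
        while start < n:
            lo = pos[start]
            end = start
            while end < n and pos[end] < lo + cfg.ld_window:
                end += 1
            yield np.arange(start, end)
            if end >= n:
                break
            start += cfg.ld_step


def _prune_window(gm, window, removed, missing, r2_max):
    active = [s for s in window if not removed[s]]
    while True:
        worst = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                if _pair_r2_or_zero(gm, active[i], active[j]) >= r2_max:
                    a, b = active[i], active[j]
                    # drop the site with more missing data; ties -> later
                    drop = b if (missing[b], b) >= (missing[a], a) else a
                    worst = drop
                    break
            if worst is not None:
                break
        if worst is None:
            return
        removed[worst] = True
        active.remove(worst)


def hwe_exact_test(genotype_counts: tuple[int, int, int]) -> float:
    """Exact two-sided Hardy-Weinberg test given (hom-ref, het, hom-alt)
    genotype counts: the p-value sums, over the distribution of heterozygote
    counts conditional on the allele counts, all outcomes no more probable
    than the observed one. Monomorphic samples return 1.0."""
    n_aa, n_ab, n_bb = genotype_counts
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one called genotype")
    k = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)  # minor allele count
    if k == 0:
        return 1.0
    hets = np.arange(k % 2, k + 1, 2)
    logp = np.array([_log_hwe_prob(n, k, h) for h in hets])
    logp -= max(logp)
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.nonzero(hets == n_ab)[0][0]]
    return float(p[p <= p_obs * (1 + 1e-12)].sum())


def _log_hwe_prob(n, k, h):
    """Log P(h heterozygotes | n diploids, minor allele count k), Levene."""
    n_minor_hom = (k - h) // 2
    n_major_hom = n - h - n_minor_hom
    return (math.lgamma(n + 1) - math.lgamma(n_minor_hom + 1)
            - math.lgamma(h + 1) - math.lgamma(n_major_hom + 1)
            + h * math.log(2))


def site_hwe_pvalue(gm: GenotypeMatrix, site: int,
                    pop: str | None = None) -> float:
    g = gm.genotypes[:, site]
    if pop is not None:
        g = g[gm.individual_index(pop=pop)]
    g = g[g != MISSING]
    if len(g) < 2:
        return 1.0
    counts = (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
    return hwe_exact_test(counts)


def filter_hwe(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Drop sites out of Hardy-Weinberg equilibrium.

    Default scope tests within each population (pooled testing would
    confound between-region structure with HWE departure) and applies a
    Bonferroni correction across sites: a site is removed when any
    population rejects at hwe_alpha / n_sites.
    """
    if gm.n_sites == 0:
        return gm
    threshold = cfg.hwe_alpha / gm.n_sites
    groups = gm.populations() if cfg.hwe_scope == "per_pop" else [None]
    keep = []
    for s in range(gm.n_sites):
        if all(site_hwe_pvalue(gm, s, pop) >= threshold for pop in groups):
            keep.append(s)
    return gm.take_sites(keep)


def run_cascade(gm: GenotypeMatrix, cfg: FilterConfig | None = None
                ) -> tuple[GenotypeMatrix, FilterLedger]:
    """Full curation cascade: biallelic -> depth/missingness -> HDplot ->
    LD pruning -> HWE, with a per-stage ledger."""
    cfg = cfg or FilterConfig()
    ledger = FilterLedger()
    n_s, n_i = gm.n_sites, gm.n_individuals
    gm = filter_biallelic(gm)
    ledger.record("biallelic", n_s, gm.n_sites, n_i, gm.n_individuals)
    gm, sub = filter_missingness_depth(gm, cfg)
    ledger.extend(sub)
    n_s = gm.n_sites
    gm = filter_hdplot(gm, cfg)
    ledger.record("hdplot", n_s, gm.n_sites, gm.n_individuals, gm.n_individuals)
    n_s = gm.n_sites
    gm = ld_prune(gm, cfg)
    ledger.record("ld_prune", n_s, gm.n_sites, gm.n_individuals, gm.n_individuals)
    n_s = gm.n_sites
    gm = filter_hwe(gm, cfg)
    ledger.record("hwe", n_s, gm.n_sites, gm.n_individuals, gm.n_individuals)
    return gm, ledger
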