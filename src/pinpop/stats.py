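"""Diversity and differentiation statistics for SNP genotype matrices.

Per-population measures: observed heterozygosity H_O, Nei-Chesser
small-sample gene diversity H_S, inbreeding coefficient F_IS (computed as
1 - mean(H_O)/mean(H_S), a ratio of site averages), per-site nucleotide
diversity pi, rarefied allelic richness, Watterson's theta and Tajima's D.
Differentiation: the Weir-Cockerham (1984) variance-component F_ST
estimator, per pair of populations and multilocus (ratio of summed
components), plus within/between-region block means of a pairwise matrix.

pi is "per site" only relative to a total callable length that includes
monomorphic positions; SNP panels do not carry that length, so it must be
supplied (defaults to the number of SNP sites, i.e. per-SNP diversity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "observed_heterozygosity", "gene_diversity_hs", "fis",
    "nucleotide_diversity", "watterson_theta", "tajimas_d", "wc_fst",
    "pairwise_fst", "region_mean_fst", "allelic_richness",
    "diversity_table",
]


def _pop_genotypes(gm: GenotypeMatrix, pop: str | None) -> np.ndarray:
    if pop is None:
        return gm.genotypes
    return gm.genotypes[gm.individual_index(pop=pop)]


def _site_counts(g: np.ndarray):
    """Per-site (called diploids, alt allele count, het count)."""
    called = (g != MISSING).sum(axis=0)
    alt = np.where(g != MISSING, g, 0).sum(axis=0)
    het = (g == 1).sum(axis=0)
    return called, alt, het


def observed_heterozygosity(gm: GenotypeMatrix, pop: str | None = None) -> float:
    """Mean over sites of the heterozygote proportion among called
    individuals of one population (or all individuals)."""
    g = _pop_genotypes(gm, pop)
    called, _, het = _site_counts(g)
    ok = called > 0
    if not ok.any():
        raise ValueError("no sites with called genotypes")
    return float((het[ok] / called[ok]).mean())


def gene_diversity_hs(gm: GenotypeMatrix, pop: str | None = None) -> float:
    """Nei-Chesser unbiased within-population gene diversity, averaged over
    sites: (n/(n-1)) * (1 - sum p^2 - H_O/(2n)) with n called diploids."""
    g = _pop_genotypes(gm, pop)
    called, alt, het = _site_counts(g)
    ok = called >= 2
    if not ok.any():
        raise ValueError("gene diversity needs sites with >= 2 called diploids")
    n = called[ok].astype(float)
    p = alt[ok] / (2 * n)
    ho = het[ok] / n
    hs = n / (n - 1) * (1 - p ** 2 - (1 - p) ** 2 - ho / (2 * n))
    return float(hs.mean())


def fis(gm: GenotypeMatrix, pop: str | None = None) -> float:
    """Inbreeding coefficient 1 - H_O/H_S at the site-averaged level;
    negative values indicate heterozygote excess."""
    hs = gene_diversity_hs(gm, pop)
    if hs == 0:
        raise ValueError("F_IS undefined when H_S = 0")
    return 1.0 - observed_heterozygosity(gm, pop) / hs


def nucleotide_diversity(gm: GenotypeMatrix, pop: str | None = None,
                         total_length: float | None = None) -> float:
    """Mean pairwise difference per site.

    Summed over SNP sites (unbiased per-site heterozygosity
    2*p*q*2n/(2n-1)) and divided by ``total_length`` callable bases;
    defaults to the number of SNP sites.
    """
    g = _pop_genotypes(gm, pop)
    if total_length is None:
        total_length = g.shape[1]
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    if total_length < g.shape[1]:
        raise ValueError("total_length shorter than the SNP panel")
    called, alt, _ = _site_counts(g)
    ok = called >= 1
    n_chrom = 2 * called[ok].astype(float)
    with np.errstate(invalid="ignore"):
        p = alt[ok] / n_chrom
        per_site = np.where(n_chrom > 1,
                            2 * p * (1 - p) * n_chrom / (n_chrom - 1), 0.0)
    return float(per_site.sum() / total_length)


def watterson_theta(s: int, n_chrom: int,
                    total_length: float | None = None) -> float:
    """Watterson's estimator S / a1, a1 the (n_chrom - 1)-th harmonic
    number; per site if total_length is given."""
    if n_chrom < 2:
        raise ValueError("need at least 2 chromosomes")
    if s < 0:
        raise ValueError("negative segregating-site count")
    a1 = np.sum(1.0 / np.arange(1, n_chrom))
    theta = s / a1
    if total_length is not None:
        theta /= total_length
    return float(theta)


def _tajima_constants(n: int):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d(gm: GenotypeMatrix, pop: str | None = None) -> float:
    """Tajima's (1989) D from the SNP panel of one population.

    Uses segregating sites within the population; the chromosome count is
    the site-average of called chromosomes (exact for complete data, an
    approximation under missingness). Raises when S = 0 (reported as NA at
    the table level).
    """
    g = _pop_genotypes(gm, pop)
    called, alt, _ = _site_counts(g)
    seg = (alt > 0) & (alt < 2 * called)
    s = int(seg.sum())
    if s == 0:
        raise ValueError("Tajima's D undefined with no segregating sites")
    n = int(round((2 * called[seg]).mean()))
    if n < 3:
        raise ValueError("Tajima's D needs >= 3 chromosomes")
    n_chrom = 2 * called[seg].astype(float)
    p = alt[seg] / n_chrom
    pi_total = float((2 * p * (1 - p) * n_chrom / (n_chrom - 1)).sum())
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    return float((pi_total - s / a1) / np.sqrt(var))


# --- Weir & Cockerham (1984) variance components ---------------------------

def _wc_components(gm: GenotypeMatrix, pops: list[str]):
    """Per-site variance components (a, b, c): among populations, among
    individuals within populations, within individuals."""
    r = len(pops)
    if r < 2:
        raise ValueError("F_ST needs at least two populations")
    counts = []
    for pop in pops:
        g = gm.genotypes[gm.individual_index(pop=pop)]
        called, alt, het = _site_counts(g)
        counts.append((called.astype(float), alt.astype(float),
                       het.astype(float)))
    n_i = np.stack([c for c, _, _ in counts])         # (r, sites) diploids
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = np.stack([a for _, a, _ in counts]) / (2 * n_i)
        h_i = np.stack([h for _, _, h in counts]) / n_i
    ok = (n_i >= 1).all(axis=0) & (n_i.sum(axis=0) > r)
    n_i, p_i, h_i = n_i[:, ok], p_i[:, ok], h_i[:, ok]
    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i ** 2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
    pq = p_bar * (1 - p_bar)
    a = (n_bar / n_c) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (pq - (r - 1) / r * s2
                                 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    poly = (p_bar > 0) & (p_bar < 1)
    return a[poly], b[poly], c[poly]


def wc_fst(gm: GenotypeMatrix, pops: list[str] | None = None) -> float:
    """Multilocus Weir-Cockerham theta: sum(a) / sum(a + b + c) over
    polymorphic sites. Small negative values are reported as computed."""
    pops = pops if pops is not None else gm.populations()
    a, b, c = _wc_components(gm, pops)
    if a.size == 0:
        raise ValueError("F_ST undefined without polymorphic sites")
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("F_ST undefined: zero total variance")
    return float(a.sum() / denom)


def pairwise_fst(gm: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric matrix of pairwise Weir-Cockerham F_ST over populations."""
    pops = gm.populations()
    out = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for i, p1 in enumerate(pops):
        out.loc[p1, p1] = 0.0
        for p2 in pops[i + 1:]:
            try:
                v = wc_fst(gm, [p1, p2])
            except ValueError:
                v = np.nan
            out.loc[p1, p2] = out.loc[p2, p1] = v
    return out


def region_mean_fst(matrix: pd.DataFrame, grouping: dict[str, str]
                    ) -> dict[str, float]:
    """Arithmetic means of the within-region and between-region blocks of a
    pairwise F_ST matrix. ``grouping`` maps population -> region."""
    regions = sorted(set(grouping.values()))
    if len(regions) != 2:
        raise ValueError("expected exactly two regions")
    ra, rb = regions
    pops_a = [p for p in matrix.index if grouping[p] == ra]
    pops_b = [p for p in matrix.index if grouping[p] == rb]
    out = {}
    for name, pops in ((f"within_{ra}", pops_a), (f"within_{rb}", pops_b)):
        if len(pops) < 2:
            out[name] = float("nan")
            continue
        vals = [matrix.loc[p1, p2] for i, p1 in enumerate(pops)
                for p2 in pops[i + 1:]]
        out[name] = float(np.mean(vals))
    out["between"] = float(np.mean(
        [matrix.loc[p1, p2] for p1 in pops_a for p2 in pops_b]))
    return out


def allelic_richness(gm: GenotypeMatrix, pop: str | None = None,
                     rarefaction_n: int = 2) -> float:
    """Mean over sites of the expected number of distinct alleles in a
    hypergeometric subsample of ``rarefaction_n`` chromosomes."""
    if rarefaction_n < 1:
        raise ValueError("rarefaction_n must be >= 1")
    g = _pop_genotypes(gm, pop)
    called, alt, _ = _site_counts(g)
    ok = 2 * called >= rarefaction_n
    if not ok.any():
        raise ValueError("rarefaction size exceeds called chromosomes everywhere")
    n = 2 * called[ok]
    k_alt = alt[ok]
    k_ref = n - k_alt
    # P(an allele with count k is absent from the subsample) = C(n-k, g)/C(n, g)
    def absent(k):
        return np.exp(_log_comb_vec(n - k, rarefaction_n)
                      - _log_comb_vec(n, rarefaction_n))
    richness = (1 - absent(k_ref)) + (1 - absent(k_alt))
    return float(richness.mean())


def _log_comb_vec(n, k):
    n = np.asarray(n, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(n < k, -np.inf, out)


@dataclass
class DiversityRow:
    population: str
    region: str
    h_o: float
    h_s: float
    f_is: float
    pi: float
    tajima_d: float
    theta_w: float


def diversity_table(gm: GenotypeMatrix, total_length: float | None = None,
                    rarefaction_n: int | None = None) -> pd.DataFrame:
    """Per-population (plus global) diversity summary."""
    rows = []
    pop_region = dict(zip(gm.pop_labels, gm.region_labels))
    for pop in gm.populations() + [None]:
        name = pop or "Global"
        region = pop_region.get(pop, "-")
        try:
            d = tajimas_d(gm, pop)
        except ValueError:
            d = np.nan
        g = _pop_genotypes(gm, pop)
        called, alt, _ = _site_counts(g)
        seg = int(((alt > 0) & (alt < 2 * called)).sum())
        n_chrom = int(round((2 * called[called > 0]).mean()))
        row = {
            "population": name, "region": region,
            "H_O": observed_heterozygosity(gm, pop),
            "H_S": gene_diversity_hs(gm, pop),
            "F_IS": fis(gm, pop),
            "pi": nucleotide_diversity(gm, pop, total_length),
            "tajima_D": d,
            "theta_W": watterson_theta(seg, n_chrom, total_length),
        }
        if rarefaction_n is not None:
            row["allelic_richness"] = allelic_richness(gm, pop, rarefaction_n)
        rows.append(row)
    return pd.DataFrame(rows)
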