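"""Joint site-frequency spectra between two region samples.

A ``JointSFS`` is a (n_A+1) x (n_B+1) matrix of site mass indexed by the
derived (or, when folded, pooled-minor) allele count in each region sample.
Missing genotypes are handled by hypergeometric projection down to a fixed
number of chromosomes per region: each site contributes its expected
subsample spectrum, so mass may be fractional. Monomorphic mass (cells
(0, 0) and (n_A, n_B)) is retained for bookkeeping; consumers that only
want segregating sites mask those corners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = ["JointSFS", "joint_sfs", "fold_sfs", "project_sfs",
           "projection_weights"]


@dataclass
class JointSFS:
    counts: np.ndarray  # (n_A+1, n_B+1) non-negative mass
    folded: bool = False
    n_reps: int | None = field(default=None, compare=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("joint SFS must be a 2-D matrix")
        if (self.counts < 0).any():
            raise ValueError("SFS mass must be non-negative")

    @property
    def shape(self):
        return self.counts.shape

    @property
    def projected_sizes(self) -> tuple[int, int]:
        """Sample sizes in chromosomes (2n_A, 2n_B)."""
        return self.counts.shape[0] - 1, self.counts.shape[1] - 1

    @property
    def monomorphic_mass(self) -> float:
        n_a, n_b = self.projected_sizes
        mass = self.counts[0, 0]
        if not self.folded:
            mass += self.counts[n_a, n_b]
        return float(mass)

    def segregating_mask(self) -> np.ndarray:
        """Boolean mask of the segregating (non-corner) cells."""
        n_a, n_b = self.projected_sizes
        mask = np.ones_like(self.counts, dtype=bool)
        mask[0, 0] = False
        mask[n_a, n_b] = False
        if self.folded:
            # folded spectra only populate the minor half
            i = np.arange(n_a + 1)[:, None]
            j = np.arange(n_b + 1)[None, :]
            mask &= (2 * (i + j) <= n_a + n_b)
        return mask

    def total(self, segregating_only: bool = True) -> float:
        if segregating_only:
            return float(self.counts[self.segregating_mask()].sum())
        return float(self.counts.sum())

    def fold(self) -> "JointSFS":
        return fold_sfs(self)

    def normalized(self, segregating_only: bool = True) -> "JointSFS":
        mask = self.segregating_mask() if segregating_only else slice(None)
        tot = self.counts[mask].sum()
        if tot <= 0:
            raise ValueError("cannot normalize an empty SFS")
        out = np.zeros_like(self.counts)
        out[mask] = self.counts[mask] / tot
        return JointSFS(out, folded=self.folded, n_reps=self.n_reps)

    def marginal(self, axis: int) -> np.ndarray:
        """1-D SFS of one region (axis 0 = region A)."""
        return self.counts.sum(axis=1 - axis)

    # --- flat-text serialisation (dadi-style) ------------------------------
    def to_text(self, path) -> None:
        n_a, n_b = self.projected_sizes
        with open(path, "w") as fh:
            fh.write(f"{n_a + 1} {n_b + 1} "
                     f"{'folded' if self.folded else 'unfolded'}\n")
            for row in self.counts:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_text(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline().split()
            rows, cols = int(header[0]), int(header[1])
            folded = header[2] == "folded"
            counts = np.loadtxt(fh, ndmin=2)
        if counts.shape != (rows, cols):
            raise ValueError(f"SFS file shape {counts.shape} does not match "
                             f"header ({rows}, {cols})")
        return cls(counts, folded=folded)


def fold_sfs(sfs: JointSFS) -> JointSFS:
    """Fold onto the pooled minor-allele orientation.

    Cell (i, j) is merged with (n_A - i, n_B - j); the orientation with the
    smaller pooled count i + j receives the mass. Cells on the exact-half
    diagonal are their own partner class: each unordered pair is kept once
    at its lexicographically smaller member.
    """
    if sfs.folded:
        warnings.warn("folding an already-folded SFS is a no-op")
        return sfs
    n_a, n_b = sfs.projected_sizes
    half = n_a + n_b
    i = np.arange(n_a + 1)[:, None]
    j = np.arange(n_b + 1)[None, :]
    pooled = 2 * (i + j)
    # keep (i, j) when its pooled count is below half, or on the exact-half
    # diagonal when it is the lexicographically smaller of the pair
    lex_smaller = (i < n_a - i) | ((i == n_a - i) & (j <= n_b - j))
    keep = (pooled < half) | ((pooled == half) & lex_smaller)
    self_comp = (2 * i == n_a) & (2 * j == n_b)
    comp = sfs.counts[::-1, ::-1]
    out = np.where(keep, sfs.counts + np.where(self_comp, 0.0, comp), 0.0)
    return JointSFS(out, folded=True, n_reps=sfs.n_reps)


def project_sfs(sfs: JointSFS, proj_a: int, proj_b: int) -> JointSFS:
    """Hypergeometric projection of an unfolded joint SFS down to
    (proj_a, proj_b) chromosomes; total mass (including any monomorphic
    corner mass) is conserved, with sites that become monomorphic in the
    subsample moving into the corner cells."""
    if sfs.folded:
        raise ValueError("project before folding")
    n_a, n_b = sfs.projected_sizes
    if proj_a > n_a or proj_b > n_b:
        raise ValueError("projection exceeds sample size")
    wa = np.stack([projection_weights(k, n_a, proj_a) for k in range(n_a + 1)])
    wb = np.stack([projection_weights(k, n_b, proj_b) for k in range(n_b + 1)])
    return JointSFS(wa.T @ sfs.counts @ wb, folded=False, n_reps=sfs.n_reps)


def projection_weights(k: int, m: int, proj: int) -> np.ndarray:
    """Hypergeometric projection of k derived among m chromosomes down to a
    subsample of ``proj``: weight[i] = P(i derived in subsample)."""
    if proj > m:
        raise ValueError("projection exceeds available chromosomes")
    i = np.arange(proj + 1)
    with np.errstate(divide="ignore"):
        logw = (_log_comb(k, i) + _log_comb(m - k, proj - i)
                - _log_comb(m, proj))
    w = np.exp(logw)
    w[(i > k) | (proj - i > m - k)] = 0.0
    return w


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def joint_sfs(gm, proj_a: int | None = None, proj_b: int | None = None,
              folded: bool = True, min_site_fraction: float = 0.9) -> JointSFS:
    """Joint SFS between the two regions of a genotype matrix.

    Each site contributes the expected spectrum of a hypergeometric
    subsample of (proj_a, proj_b) chromosomes from its called chromosomes;
    sites with fewer called chromosomes than the projection are dropped.
    If projection sizes are omitted, the largest sizes retaining at least
    ``min_site_fraction`` of sites are chosen. Allele counts are of the
    alternate allele (reference orientation); fold for the minor-allele
    spectrum.
    """
    called_a, alt_a = _region_counts(gm, region_index=0)
    called_b, alt_b = _region_counts(gm, region_index=1)
    if proj_a is None:
        proj_a = _auto_projection(called_a, min_site_fraction)
    if proj_b is None:
        proj_b = _auto_projection(called_b, min_site_fraction)
    if proj_a < 2 or proj_b < 2:
        raise ValueError("projection sizes must be >= 2")
    keep = (called_a >= proj_a) & (called_b >= proj_b)
    if not keep.any():
        raise ValueError("projection exceeds available chromosomes at every site")
    counts = np.zeros((proj_a + 1, proj_b + 1))
    for s in np.nonzero(keep)[0]:
        wa = projection_weights(int(alt_a[s]), int(called_a[s]), proj_a)
        wb = projection_weights(int(alt_b[s]), int(called_b[s]), proj_b)
        counts += np.outer(wa, wb)
    out = JointSFS(counts, folded=False)
    if folded:
        out = out.fold()
    return out


def _region_counts(gm, region_index: int):
    """(called_chromosomes, alt_allele_count) per site for one region."""
    regions = sorted(set(gm.region_labels))
    if len(regions) != 2:
        raise ValueError("joint SFS requires exactly two regions")
    # keep declared order if the matrix provides one
    region = gm.region_order()[region_index]
    sel = np.array([r == region for r in gm.region_labels])
    g = gm.genotypes[sel]
    called = 2 * (g >= 0).sum(axis=0)
    alt = np.where(g >= 0, g, 0).sum(axis=0)
    return called, alt


def _auto_projection(called: np.ndarray, min_site_fraction: float) -> int:
    """Largest projection size keeping >= min_site_fraction of sites."""
    if called.size == 0:
        raise ValueError("no sites")
    for proj in range(int(called.max()), 1, -1):
        if (called >= proj).mean() >= min_site_fraction:
            return proj
    return 2
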