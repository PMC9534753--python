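"""Low-level structured-coalescent kernels (numba-compiled).

Two demes (0 and 1) plus an ancestral merge, piecewise-constant diploid
sizes and backward-in-time per-lineage migration rates, expressed as a
sequence of epochs on the backward time axis:

    t_end[e]   -- end of epoch e in generations (last entry is +inf)
    N0[e], N1[e] -- diploid deme sizes during epoch e
    m0[e], m1[e] -- per-generation probability that a lineage currently in
                    deme 0 (resp. 1) traces its ancestry to the other deme
    merged[e]  -- 1 if, at the start of epoch e, all lineages are moved to
                  deme 0 (the ancestral deme); migration is then irrelevant

Branch lengths are accumulated into a matrix M indexed by the number of
sample chromosomes a branch subtends in deme 0 (rows) and deme 1 (cols).
Under the infinite-sites model, E[M[i, j]] * mu is the per-site probability
of a segregating site with derived counts (i, j).

All kernels draw from numba's internal np.random state; callers must seed
via the ``seed`` argument for reproducibility.
"""

import numpy as np
from numba import njit

__all__ = [
    "branch_length_matrix",
    "sample_site_counts",
    "sample_site_leafsets",
]


@njit(cache=True)
def _pick_in_deme(deme, n_alive, d, r):
    """Index of the r-th (0-based) alive lineage currently in deme d."""
    c = -1
    for i in range(n_alive):
        if deme[i] == d:
            c += 1
            if c == r:
                return i
    return -1  # unreachable for valid r


@njit(cache=True)
def _simulate_genealogy(nA, nB, t_end, N0, N1, m0, m1, merged,
                        M, deme, a, b, birth, leafsets, leaf_buf,
                        branch_len, branch_a, branch_b, track_leaves):
    """Simulate one genealogy; accumulate branch lengths into M.

    If track_leaves is true, every non-root branch is also appended to
    (branch_len, branch_a, branch_b, leaf_buf) so a mutation can later be
    dropped on a length-weighted branch. Returns (total_length, n_branches).
    """
    n = nA + nB
    for i in range(n):
        deme[i] = 0 if i < nA else 1
        a[i] = 1 if i < nA else 0
        b[i] = 0 if i < nA else 1
        birth[i] = 0.0
        if track_leaves:
            for j in range(n):
                leafsets[i, j] = 0
            leafsets[i, i] = 1
    n_alive = n
    k0 = nA
    k1 = nB
    t = 0.0
    e = 0
    if merged[0] == 1:
        for i in range(n_alive):
            deme[i] = 0
        k0 = n_alive
        k1 = 0
    total_len = 0.0
    n_branch = 0
    while n_alive > 1:
        c0 = k0 * (k0 - 1) / (4.0 * N0[e])
        c1 = k1 * (k1 - 1) / (4.0 * N1[e])
        g0 = 0.0 if merged[e] == 1 else k0 * m0[e]
        g1 = 0.0 if merged[e] == 1 else k1 * m1[e]
        rate = c0 + c1 + g0 + g1
        if rate <= 0.0:
            # nothing can happen in this epoch; jump to the next boundary
            t = t_end[e]
            e += 1
            if merged[e] == 1 and k1 > 0:
                for i in range(n_alive):
                    deme[i] = 0
                k0 = n_alive
                k1 = 0
            continue
        dt = np.random.exponential(1.0 / rate)
        if t + dt >= t_end[e]:
            t = t_end[e]
            e += 1
            if merged[e] == 1 and k1 > 0:
                for i in range(n_alive):
                    deme[i] = 0
                k0 = n_alive
                k1 = 0
            continue
        t += dt
        u = np.random.random() * rate
        if u < c0 or u < c0 + c1:
            d = 0 if u < c0 else 1
            kd = k0 if d == 0 else k1
            r1 = int(np.random.random() * kd)
            r2 = int(np.random.random() * (kd - 1))
            if r2 >= r1:
                r2 += 1
            i1 = _pick_in_deme(deme, n_alive, d, r1)
            i2 = _pick_in_deme(deme, n_alive, d, r2)
            # record both child branches
            for idx in (i1, i2):
                blen = t - birth[idx]
                M[a[idx], b[idx]] += blen
                total_len += blen
                if track_leaves:
                    branch_len[n_branch] = blen
                    branch_a[n_branch] = a[idx]
                    branch_b[n_branch] = b[idx]
                    for j in range(n):
                        leaf_buf[n_branch, j] = leafsets[idx, j]
                    n_branch += 1
            # merge i2 into i1
            a[i1] += a[i2]
            b[i1] += b[i2]
            birth[i1] = t
            if track_leaves:
                for j in range(n):
                    leafsets[i1, j] |= leafsets[i2, j]
            # swap-remove i2
            last = n_alive - 1
            deme[i2] = deme[last]
            a[i2] = a[last]
            b[i2] = b[last]
            birth[i2] = birth[last]
            if track_leaves:
                for j in range(n):
                    leafsets[i2, j] = leafsets[last, j]
            n_alive -= 1
            if d == 0:
                k0 -= 1
            else:
                k1 -= 1
        elif u < c0 + c1 + g0:
            r = int(np.random.random() * k0)
            i1 = _pick_in_deme(deme, n_alive, 0, r)
            deme[i1] = 1
            k0 -= 1
            k1 += 1
        else:
            r = int(np.random.random() * k1)
            i1 = _pick_in_deme(deme, n_alive, 1, r)
            deme[i1] = 0
            k0 += 1
            k1 -= 1
    return total_len, n_branch


@njit(cache=True)
def branch_length_matrix(nA, nB, t_end, N0, N1, m0, m1, merged, reps, seed):
    """Mean branch-length matrix over `reps` independent genealogies.

    Entry (i, j) is the expected total length (generations) of branches
    subtending i of the nA deme-0 chromosomes and j of the nB deme-1
    chromosomes. The root branch carries no length.
    """
    np.random.seed(seed)
    n = nA + nB
    M = np.zeros((nA + 1, nB + 1))
    deme = np.empty(n, dtype=np.int8)
    a = np.empty(n, dtype=np.int64)
    b = np.empty(n, dtype=np.int64)
    birth = np.empty(n, dtype=np.float64)
    dummy_ls = np.empty((1, 1), dtype=np.uint8)
    dummy_lb = np.empty((1, 1), dtype=np.uint8)
    dummy_bl = np.empty(1, dtype=np.float64)
    dummy_ba = np.empty(1, dtype=np.int64)
    for _ in range(reps):
        _simulate_genealogy(nA, nB, t_end, N0, N1, m0, m1, merged,
                            M, deme, a, b, birth, dummy_ls, dummy_lb,
                            dummy_bl, dummy_ba, dummy_ba, False)
    return M / reps


@njit(cache=True)
def sample_site_counts(nA, nB, t_end, N0, N1, m0, m1, merged,
                       n_sites, t_cap, seed):
    """Draw derived-allele count pairs for n_sites unlinked segregating sites.

    A site's genealogy is length-biased (longer trees are likelier to carry
    a mutation), realised here by rejection with envelope t_cap; genealogies
    longer than t_cap are accepted outright, so t_cap should be a generous
    upper bound on total tree length. Within an accepted genealogy the
    mutated branch is chosen with probability proportional to its length.

    Returns (ia, ib, mean_total_length, max_total_length) where ia/ib are
    the deme-0/deme-1 derived counts per site and the lengths summarise the
    *unconditional* genealogy length distribution (for callers that need to
    convert a segregating-site count into an implied sequence length).
    """
    np.random.seed(seed)
    n = nA + nB
    Mg = np.zeros((nA + 1, nB + 1))
    deme = np.empty(n, dtype=np.int8)
    a = np.empty(n, dtype=np.int64)
    b = np.empty(n, dtype=np.int64)
    birth = np.empty(n, dtype=np.float64)
    dummy_ls = np.empty((1, 1), dtype=np.uint8)
    dummy_lb = np.empty((1, 1), dtype=np.uint8)
    dummy_bl = np.empty(1, dtype=np.float64)
    dummy_ba = np.empty(1, dtype=np.int64)
    ia = np.empty(n_sites, dtype=np.int64)
    ib = np.empty(n_sites, dtype=np.int64)
    got = 0
    len_sum = 0.0
    len_max = 0.0
    n_trees = 0
    while got < n_sites:
        for i in range(nA + 1):
            for j in range(nB + 1):
                Mg[i, j] = 0.0
        tot, _ = _simulate_genealogy(nA, nB, t_end, N0, N1, m0, m1, merged,
                                     Mg, deme, a, b, birth, dummy_ls,
                                     dummy_lb, dummy_bl, dummy_ba, dummy_ba,
                                     False)
        n_trees += 1
        len_sum += tot
        if tot > len_max:
            len_max = tot
        if np.random.random() * t_cap >= tot:
            continue
        # choose the mutated branch class proportional to branch length
        u = np.random.random() * tot
        acc = 0.0
        done = False
        for i in range(nA + 1):
            if done:
                break
            for j in range(nB + 1):
                acc += Mg[i, j]
                if acc >= u:
                    ia[got] = i
                    ib[got] = j
                    done = True
                    break
        if not done:  # numerical edge: put it in the last non-empty class
            ia[got] = nA
            ib[got] = nB - 1
        got += 1
    return ia, ib, len_sum / n_trees, len_max


@njit(cache=True)
def sample_site_leafsets(nA, nB, t_end, N0, N1, m0, m1, merged,
                         n_sites, t_cap, seed):
    """Like sample_site_counts but returns the derived-carrier indicator per
    chromosome: a (n_sites, nA+nB) uint8 matrix (deme-0 chromosomes first).
    """
    np.random.seed(seed)
    n = nA + nB
    max_branch = 2 * n  # <= 2n-2 non-root branches
    Mg = np.zeros((nA + 1, nB + 1))
    deme = np.empty(n, dtype=np.int8)
    a = np.empty(n, dtype=np.int64)
    b = np.empty(n, dtype=np.int64)
    birth = np.empty(n, dtype=np.float64)
    leafsets = np.empty((n, n), dtype=np.uint8)
    leaf_buf = np.empty((max_branch, n), dtype=np.uint8)
    branch_len = np.empty(max_branch, dtype=np.float64)
    branch_a = np.empty(max_branch, dtype=np.int64)
    branch_b = np.empty(max_branch, dtype=np.int64)
    out = np.zeros((n_sites, n), dtype=np.uint8)
    got = 0
    while got < n_sites:
        for i in range(nA + 1):
            for j in range(nB + 1):
                Mg[i, j] = 0.0
        tot, nbr = _simulate_genealogy(nA, nB, t_end, N0, N1, m0, m1, merged,
                                       Mg, deme, a, b, birth, leafsets,
                                       leaf_buf, branch_len, branch_a,
                                       branch_b, True)
        if np.random.random() * t_cap >= tot:
            continue
        u = np.random.random() * tot
        acc = 0.0
        chosen = nbr - 1
        for i in range(nbr):
            acc += branch_len[i]
            if acc >= u:
                chosen = i
                break
        for j in range(n):
            out[got, j] = leaf_buf[chosen, j]
        got += 1
    return out
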