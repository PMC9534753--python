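"""Composite-likelihood fitting of demographic scenarios to a joint SFS,
AIC/wAIC model ranking, and parametric-bootstrap confidence intervals.

The likelihood treats SNPs as independent draws from the expected joint
spectrum (a composite likelihood: linkage is ignored). Two data modes are
supported and detected from the observed spectrum:

* conditional — the observed SFS holds segregating sites only; expected
  proportions are normalised over segregating cells. Absolute sizes are
  then not identified (only ratios of sizes, times and scaled migration
  rates), which is the classic SNP-panel caveat.
* absolute — the observed SFS additionally carries the monomorphic site
  count in its (0, 0) corner (sequence length bookkeeping); together with
  the mutation rate this pins the absolute parameter scale.

Optimisation is a multi-start cyclic coordinate search (ECM-style): each
free parameter in turn is optimised on its search range by a coarse grid
plus one local refinement, holding the others fixed, with common random
numbers within a cycle so Monte-Carlo noise cancels out of comparisons.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .demography import (
    MU_PER_GENERATION,
    DemographicModel,
    SearchRanges,
    expected_sfs,
    simulate_sfs_counts,
)
from .sfs import JointSFS

__all__ = [
    "FitSettings", "FitResult", "BootstrapResult", "composite_loglik",
    "maximize", "model_select", "parametric_bootstrap",
    "attach_monomorphic_mass",
]


@dataclass
class FitSettings:
    n_starts: int = 10
    n_cycles: int = 10
    reps_per_eval: int = 10_000
    reps_final: Optional[int] = None      # default 4x reps_per_eval
    grid_points: int = 7
    refine_points: int = 5
    n_screen: int = 20                    # random draws screened per start slot
    scale_moves: bool = True              # joint (c*N, c*T, m/c) ridge moves
    seed: int = 0
    mu: float = MU_PER_GENERATION
    gen_time: float = 40.0
    anc_policy: str = "sum"               # "sum" or "free"
    p_min: Optional[float] = None         # zero-cell floor; default 1/(10*reps)
    pool_below: float = 3.0               # pool obs cells with less mass
    polish: bool = True                   # Nelder-Mead polish of the best start
    polish_maxfev: int = 250
    profile_param: Optional[str] = "t_div"  # weakly-identified ridge direction
    profile_points: int = 7
    profile_window: float = 3.0           # grid spans value/window..value*window
    profile_maxfev: int = 100

    def __post_init__(self):
        if min(self.n_starts, self.n_cycles, self.reps_per_eval) < 1:
            raise ValueError("n_starts, n_cycles, reps_per_eval must be >= 1")
        if self.anc_policy not in ("sum", "free"):
            raise ValueError("anc_policy must be 'sum' or 'free'")
        if self.reps_final is None:
            self.reps_final = 4 * self.reps_per_eval


@dataclass
class FitResult:
    scenario: str
    params: dict
    max_lnl: float
    k: int
    n_restarts: int
    convergence_trace: list
    converged: bool
    obs_hash: str
    seed: int
    aic: float = math.nan
    delta_aic: float = math.nan
    waic: float = math.nan
    at_bound: list = field(default_factory=list)

    @property
    def model(self) -> DemographicModel:
        return _build_model(self.scenario, self.params)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class BootstrapResult:
    point: dict
    ci: dict                    # parameter -> (2.5%, 97.5%)
    replicates: dict            # parameter -> list of B' estimates
    n_requested: int
    n_converged: int


def _sfs_hash(obs: JointSFS) -> str:
    h = hashlib.sha256(obs.counts.tobytes())
    h.update(b"folded" if obs.folded else b"unfolded")
    return h.hexdigest()[:16]


def attach_monomorphic_mass(sfs: JointSFS, total_length: float) -> JointSFS:
    """Place the monomorphic site count implied by ``total_length`` callable
    bases into the (0, 0) corner, switching the spectrum to absolute mode."""
    seg = sfs.total(segregating_only=True)
    if total_length < seg:
        raise ValueError("total_length smaller than the segregating count")
    counts = sfs.counts.copy()
    counts[0, 0] += total_length - sfs.counts.sum()
    return JointSFS(counts, folded=sfs.folded, n_reps=sfs.n_reps)


def composite_loglik(obs: JointSFS, expected: JointSFS,
                     p_min: float | None = None,
                     pool_below: float = 0.0) -> float:
    """Sum over cells of observed mass times log expected probability.

    Zero-expectation segregating cells are floored at p_min (default
    1/(10 * n_reps) of the expected spectrum) and the segregating block is
    renormalised to its pre-floor mass. In absolute mode (monomorphic mass
    present in both spectra) the monomorphic cell contributes too.

    ``pool_below`` coarsens the multinomial: segregating cells whose
    *observed* mass is below the threshold are merged into one aggregate
    category (expected probabilities summed). Because the pooling is
    defined by the data it is identical for every candidate model, and it
    greatly reduces the noise and downward bias that sparsely-estimated
    cells inject into a Monte-Carlo likelihood.
    """
    if obs.shape != expected.shape or obs.folded != expected.folded:
        raise ValueError("observed and expected SFS dimensions/folding differ")
    if obs.counts.sum() <= 0:
        raise ValueError("empty observed SFS")
    if p_min is None:
        p_min = 1.0 / (10 * expected.n_reps) if expected.n_reps else 1e-8
    mask = obs.segregating_mask()
    m = obs.counts[mask]
    p = expected.counts[mask].astype(float)
    seg_mass = p.sum()
    if seg_mass <= 0:
        raise ValueError("expected SFS has no segregating mass")
    if pool_below > 0:
        rare = m < pool_below
        if rare.any() and (~rare).any():
            m = np.append(m[~rare], m[rare].sum())
            p = np.append(p[~rare], p[rare].sum())
    p = np.maximum(p, p_min)
    p *= seg_mass / p.sum()
    absolute = expected.monomorphic_mass > 0
    if absolute:
        lnl = float((m * np.log(p)).sum())
        m_mono = obs.monomorphic_mass
        if m_mono > 0:
            lnl += m_mono * math.log(expected.monomorphic_mass)
    else:
        lnl = float((m * np.log(p / seg_mass)).sum())
    return lnl


def _build_model(scenario: str, params: dict,
                 mu: float = MU_PER_GENERATION,
                 gen_time: float = 40.0) -> DemographicModel:
    fields = dict(params)
    fields.setdefault("mu", mu)
    fields.setdefault("gen_time", gen_time)
    return DemographicModel(scenario=scenario, **fields)


def _constrained_bounds(name: str, lo: float, hi: float, params: dict):
    """Keep contraction times strictly inside (0, T_DIV)."""
    if name in ("t_con_smo", "t_con_chd"):
        hi = min(hi, 0.99 * params["t_div"])
    if name == "t_div":
        t_cons = [params.get("t_con_smo"), params.get("t_con_chd")]
        floor = max((t for t in t_cons if t is not None), default=0.0)
        lo = max(lo, floor / 0.99 + 1e-9)
    return lo, hi


def _zoom_window(center: float, lo: float, hi: float, frac: float,
                 log: bool) -> tuple[float, float]:
    """Sub-window of [lo, hi] of relative width ``frac`` around center."""
    frac = max(frac, 0.02)
    if log:
        llo, lhi, lc = math.log(lo), math.log(hi), math.log(center)
        half = 0.5 * frac * (lhi - llo)
        a, b = max(llo, lc - half), min(lhi, lc + half)
        return math.exp(a), math.exp(b)
    half = 0.5 * frac * (hi - lo)
    return max(lo, center - half), min(hi, center + half)


def _grid(lo: float, hi: float, n: int, log: bool) -> np.ndarray:
    if log:
        return np.exp(np.linspace(math.log(lo), math.log(hi), n))
    return np.linspace(lo, hi, n)


def maximize(obs: JointSFS, scenario: str, ranges: SearchRanges,
             settings: FitSettings | None = None) -> FitResult:
    """Maximum composite-likelihood fit of one scenario to an observed SFS.

    Starting points are drawn from the search priors (log-uniform for
    migration); each is refined by cyclic per-parameter grid maximisation.
    All replicates of a given (seed, settings) pair are deterministic.
    """
    settings = settings or FitSettings()
    n_a, n_b = obs.projected_sizes
    free = _build_model(scenario, _placeholder_params(scenario, ranges),
                        settings.mu, settings.gen_time).free_parameters(
                            anc_free=settings.anc_policy == "free")
    absolute = obs.monomorphic_mass > 0
    mode = "absolute" if absolute else "conditional"
    obs_hash = _sfs_hash(obs)
    rng = np.random.default_rng(settings.seed)

    def evaluate(params: dict, eval_seed: int, reps: int) -> float:
        model = _build_model(scenario, params, settings.mu, settings.gen_time)
        exp = expected_sfs(model, n_a, n_b, reps, eval_seed, mode=mode,
                           folded=obs.folded)
        return composite_loglik(obs, exp, settings.p_min,
                                settings.pool_below)

    # screening: many cheap evaluations of prior draws, best ones become
    # starting points (common random numbers across all screened draws)
    starts = []
    if settings.n_screen > 0:
        n_cand = settings.n_screen * settings.n_starts
        cands = []
        for _ in range(n_cand):
            p = ranges.draw(free, rng)
            _enforce_time_order(p)
            cands.append(p)
        screen_seed = (settings.seed * 524_287 + 11) % (2 ** 31)
        screen_reps = max(200, settings.reps_per_eval // 5)
        scores = [evaluate(p, screen_seed, screen_reps) for p in cands]
        order = np.argsort(scores)[::-1]
        # pick the best candidates subject to spread along the weakly
        # identified direction, so near-tied likelihood basins (e.g. low
        # T with low migration vs high T with migration) all get a start
        spread_on = (settings.profile_param
                     if settings.profile_param in free else free[0])
        lo_s, hi_s, _ = ranges[spread_on]
        min_gap = (hi_s - lo_s) / (2.0 * settings.n_starts)
        for i in order:
            v = cands[i][spread_on]
            if all(abs(v - s[spread_on]) >= min_gap for s in starts):
                starts.append(cands[i])
            if len(starts) == settings.n_starts:
                break
        for i in order:  # top up if the spread constraint was too strict
            if len(starts) == settings.n_starts:
                break
            if cands[i] not in starts:
                starts.append(cands[i])
    else:
        for _ in range(settings.n_starts):
            p = ranges.draw(free, rng)
            _enforce_time_order(p)
            starts.append(p)

    best_per_start = []
    traces = []
    for start, start_params in enumerate(starts):
        params = dict(start_params)
        trace = []
        for cycle in range(settings.n_cycles):
            cycle_seed = (settings.seed * 1_000_003 + start * 7919
                          + cycle * 104_729 + 1) % (2 ** 31)
            cache: dict = {}

            def ev(p):
                key = tuple(round(p[name], 10) for name in free)
                if key not in cache:
                    cache[key] = evaluate(p, cycle_seed, settings.reps_per_eval)
                return cache[key]

            current_lnl = ev(params)
            for name in free:
                lo, hi, prior = ranges[name]
                lo, hi = _constrained_bounds(name, lo, hi, params)
                log_scale = prior == "log_uniform"
                # cycle 0 sweeps the whole range; later cycles zoom in on a
                # window around the current value that shrinks geometrically
                if cycle == 0:
                    g_lo, g_hi = lo, hi
                else:
                    g_lo, g_hi = _zoom_window(params[name], lo, hi,
                                              0.6 ** cycle, log_scale)
                cand = list(_grid(g_lo, g_hi, settings.grid_points, log_scale))
                cand.append(params[name])
                vals = []
                for v in cand:
                    trial = dict(params)
                    trial[name] = v
                    vals.append(ev(trial))
                order = np.argsort(cand)
                cand_s = [cand[i] for i in order]
                vals_s = [vals[i] for i in order]
                b = int(np.argmax(vals_s))
                # refine between the neighbours of the best grid point
                r_lo = cand_s[max(b - 1, 0)]
                r_hi = cand_s[min(b + 1, len(cand_s) - 1)]
                if r_hi > r_lo and settings.refine_points > 0:
                    for v in _grid(r_lo, r_hi, settings.refine_points,
                                   log_scale):
                        trial = dict(params)
                        trial[name] = float(v)
                        lnl = ev(trial)
                        if lnl > vals_s[b] + 1e-12:
                            vals_s[b] = lnl
                            cand_s[b] = float(v)
                params[name] = float(cand_s[b])
                current_lnl = vals_s[b]
            if settings.scale_moves:
                params, current_lnl = _scale_move(params, free, ranges, ev,
                                                  current_lnl)
            trace.append(current_lnl)
        best_per_start.append(dict(params))
        traces.append(trace)

    # compare start endpoints under one common, larger evaluation batch
    final_seed = (settings.seed * 6_700_417 + 3) % (2 ** 31)
    finals = [evaluate(p, final_seed, settings.reps_final)
              for p in best_per_start]
    ibest = int(np.argmax(finals))
    params = best_per_start[ibest]
    if settings.polish:
        # simplex polish crosses diagonal ridges (e.g. T_DIV vs migration)
        # that per-coordinate moves zigzag along; the fixed-seed Monte-Carlo
        # surface is deterministic, so a derivative-free method applies
        polish_seed = (settings.seed * 15_485_863 + 7) % (2 ** 31)
        polish_reps = 2 * settings.reps_per_eval
        params, _ = _nelder_mead_polish(
            params, free, ranges,
            lambda p: evaluate(p, polish_seed, polish_reps),
            settings.polish_maxfev)
        if (settings.profile_param in free
                and settings.profile_points > 0):
            # walk the near-flat ridge: grid the weak parameter and
            # re-optimise the rest at each grid value, keeping the best
            params = _profile_walk(
                params, free, ranges, settings,
                lambda p: evaluate(p, polish_seed, settings.reps_per_eval))
            # the walk moves along the ridge at fixed grid values; a second
            # polish releases all coordinates from the best point found
            params, _ = _nelder_mead_polish(
                params, free, ranges,
                lambda p: evaluate(p, polish_seed, polish_reps),
                settings.polish_maxfev)
        finals[ibest] = evaluate(params, final_seed, settings.reps_final)
    converged = len(traces[ibest]) > 0 and np.isfinite(finals[ibest])
    at_bound = []
    for name in free:
        lo, hi, prior = ranges[name]
        span = (math.log(hi / lo) if prior == "log_uniform" else hi - lo)
        v = (math.log(params[name] / lo) if prior == "log_uniform"
             else params[name] - lo)
        if v < 1e-3 * span or v > (1 - 1e-3) * span:
            at_bound.append(name)
    return FitResult(
        scenario=scenario, params=params, max_lnl=float(finals[ibest]),
        k=len(free), n_restarts=settings.n_starts, convergence_trace=traces,
        converged=bool(converged), obs_hash=obs_hash, seed=settings.seed,
        at_bound=at_bound)


_SIZE_TIME_PARAMS = ("n_smo", "n_chd", "n_smo_pre", "n_chd_pre", "n_anc",
                     "t_div", "t_con_smo", "t_con_chd")
_MIGRATION_PARAMS = ("m_smo_to_chd", "m_chd_to_smo")


def _scale_move(params, free, ranges, ev, current_lnl):
    """Line search along the coalescent scaling ridge.

    The conditional SFS is invariant under (c*N, c*T, m/c); only the
    monomorphic/theta term breaks the tie, so coordinate moves crawl along
    this ridge. A joint rescale escapes it in one step. The factor range is
    restricted so every parameter stays inside its search box.
    """
    c_lo, c_hi = 0.25, 4.0
    for name in free:
        lo, hi, _ = ranges[name]
        v = params[name]
        if name in _SIZE_TIME_PARAMS:
            c_lo, c_hi = max(c_lo, lo / v), min(c_hi, hi / v)
        elif name in _MIGRATION_PARAMS and v > 0:
            c_lo, c_hi = max(c_lo, v / hi), min(c_hi, v / lo)
    if not c_lo < c_hi:
        return params, current_lnl
    best = params
    for c in np.exp(np.linspace(math.log(c_lo), math.log(c_hi), 9)):
        trial = dict(params)
        for name in free:
            if name in _SIZE_TIME_PARAMS:
                trial[name] = params[name] * c
            elif name in _MIGRATION_PARAMS:
                trial[name] = params[name] / c
        lnl = ev(trial)
        if lnl > current_lnl:
            best, current_lnl = trial, lnl
    return dict(best), current_lnl


def _profile_walk(params, free, ranges, settings, evaluate):
    """Grid one weakly-identified parameter (geometric spacing around its
    current value) and re-optimise the remaining parameters at each grid
    value with a short simplex run; returns the best point found."""
    name = settings.profile_param
    lo, hi, _ = ranges[name]
    lo, hi = _constrained_bounds(name, lo, hi, params)
    center = params[name]
    g_lo = max(lo, center / settings.profile_window)
    g_hi = min(hi, center * settings.profile_window)
    others = [n for n in free if n != name]
    grid = np.exp(np.linspace(math.log(g_lo), math.log(g_hi),
                              settings.profile_points))
    best_params = dict(params)
    best_lnl = evaluate(params)

    def refit_at(v, warm):
        trial = dict(warm)
        trial[name] = float(v)
        _enforce_time_order(trial)
        if not others:
            return trial, evaluate(trial)

        def eval_at(p, _v=float(v)):
            full = {**p, name: _v}
            _enforce_time_order(full)
            return evaluate(full)

        refined, lnl = _nelder_mead_polish(
            trial, others, ranges, eval_at, settings.profile_maxfev)
        refined[name] = float(v)
        return refined, lnl

    # continuation: walk outward from the current optimum in each
    # direction, warm-starting each grid point from its neighbour so the
    # compensating parameters track the ridge
    above = sorted(v for v in grid if v > center)
    below = sorted((v for v in grid if v <= center), reverse=True)
    for chain in (above, below):
        warm = dict(params)
        for v in chain:
            warm, lnl = refit_at(v, warm)
            if lnl > best_lnl:
                best_params, best_lnl = dict(warm), lnl
    return best_params


def _nelder_mead_polish(params, free, ranges, evaluate, maxfev):
    """Local simplex maximisation in box-normalised coordinates (log scale
    for log-uniform parameters); values are clipped back into the box and
    time-order constraints are re-imposed on every evaluation."""
    from scipy.optimize import minimize

    def encode(p):
        x = []
        for name in free:
            lo, hi, prior = ranges[name]
            v = min(max(p[name], lo), hi)
            if prior == "log_uniform":
                x.append((math.log(v) - math.log(lo))
                         / (math.log(hi) - math.log(lo)))
            else:
                x.append((v - lo) / (hi - lo))
        return np.array(x)

    def decode(x):
        p = {}
        for name, xi in zip(free, x):
            lo, hi, prior = ranges[name]
            xi = min(max(float(xi), 0.0), 1.0)
            if prior == "log_uniform":
                p[name] = math.exp(math.log(lo)
                                   + xi * (math.log(hi) - math.log(lo)))
            else:
                p[name] = lo + xi * (hi - lo)
        _enforce_time_order(p)
        return p

    x0 = encode(params)
    simplex = [x0]
    for i in range(len(x0)):
        v = x0.copy()
        v[i] = v[i] + 0.08 if v[i] <= 0.9 else v[i] - 0.08
        simplex.append(v)
    res = minimize(lambda x: -evaluate(decode(x)), x0,
                   method="Nelder-Mead",
                   options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 0.05,
                            "initial_simplex": np.array(simplex)})
    best = decode(res.x)
    return best, -res.fun


def _placeholder_params(scenario: str, ranges: SearchRanges) -> dict:
    out = {"n_smo": 500.0, "n_chd": 500.0, "t_div": 1000.0}
    if scenario in ("CON", "CON_M"):
        out.update(n_smo_pre=500.0, n_chd_pre=500.0,
                   t_con_smo=100.0, t_con_chd=100.0)
    if scenario in ("DIV_M", "CON_M"):
        out.update(m_smo_to_chd=1e-6, m_chd_to_smo=1e-6)
    return out


def _enforce_time_order(params: dict) -> None:
    t_div = params.get("t_div")
    if t_div is None:
        return
    for name in ("t_con_smo", "t_con_chd"):
        if name in params and params[name] >= t_div:
            params[name] = 0.5 * t_div


def model_select(fits: list[FitResult]) -> list[FitResult]:
    """Rank fits of competing scenarios on the same observed SFS by AIC and
    attach delta-AIC and Akaike weights."""
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    if len({f.obs_hash for f in fits}) != 1:
        raise ValueError("fits were made on different observed spectra")
    for f in fits:
        f.aic = 2 * f.k - 2 * f.max_lnl
    amin = min(f.aic for f in fits)
    for f in fits:
        f.delta_aic = f.aic - amin
    weights = np.array([math.exp(-f.delta_aic / 2) for f in fits])
    weights /= weights.sum()
    for f, w in zip(fits, weights):
        f.waic = float(w)
    return sorted(fits, key=lambda f: f.aic)


def parametric_bootstrap(mle_model: DemographicModel, n_a: int, n_b: int,
                         n_snps: int, b_reps: int, ranges: SearchRanges,
                         settings: FitSettings | None = None,
                         folded: bool = True) -> BootstrapResult:
    """Percentile confidence intervals from refits of SFS data simulated
    under the fitted model. Non-convergent replicates are excluded from the
    percentiles and counted."""
    if b_reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    settings = settings or FitSettings()
    free = mle_model.free_parameters(anc_free=settings.anc_policy == "free")
    reps: dict[str, list[float]] = {name: [] for name in free}
    n_conv = 0
    for b in range(b_reps):
        seed_b = (settings.seed * 2_000_003 + 101 * b + 17) % (2 ** 31)
        sfs, length = simulate_sfs_counts(mle_model, n_a, n_b, n_snps,
                                          seed_b, folded=folded)
        obs = attach_monomorphic_mass(sfs, length)
        fit = maximize(obs, mle_model.scenario, ranges,
                       _reseeded(settings, seed_b))
        if not fit.converged:
            continue
        n_conv += 1
        for name in free:
            reps[name].append(fit.params[name])
    ci = {}
    for name in free:
        vals = np.array(reps[name])
        if len(vals):
            ci[name] = (float(np.percentile(vals, 2.5)),
                        float(np.percentile(vals, 97.5)))
        else:
            ci[name] = (math.nan, math.nan)
    point = {name: getattr(mle_model, name) for name in free}
    return BootstrapResult(point=point, ci=ci, replicates=reps,
                           n_requested=b_reps, n_converged=n_conv)


def _reseeded(settings: FitSettings, seed: int) -> FitSettings:
    out = FitSettings(**{**asdict(settings), "seed": int(seed)})
    return out
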