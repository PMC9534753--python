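import math

import numpy as np
import pytest

from pinpop.demography import (DemographicModel, SearchRanges,
                               simulate_sfs_counts)
from pinpop.inference import (
    BootstrapResult, FitResult, FitSettings, attach_monomorphic_mass,
    composite_loglik, maximize, model_select, parametric_bootstrap,
)
from pinpop.sfs import JointSFS


def _two_cell_obs(m01, m10):
    counts = np.zeros((2, 2))
    counts[0, 1] = m01
    counts[1, 0] = m10
    return JointSFS(counts)


def _two_cell_expected(p01, p10):
    counts = np.zeros((2, 2))
    counts[0, 1] = p01
    counts[1, 0] = p10
    return JointSFS(counts)


class TestCompositeLoglik:
    def test_multinomial_arithmetic(self):
        obs = _two_cell_obs(3, 1)
        exp = _two_cell_expected(0.75, 0.25)
        assert composite_loglik(obs, exp) == pytest.approx(
            3 * math.log(0.75) + math.log(0.25))

    def test_single_populated_cell_zero_loglik(self):
        obs = _two_cell_obs(5, 0)
        exp = _two_cell_expected(1.0, 0.0)
        assert composite_loglik(obs, exp) == pytest.approx(0.0, abs=1e-6)

    def test_maximised_when_expected_proportional_to_observed(self):
        obs = _two_cell_obs(7, 3)
        best = composite_loglik(obs, _two_cell_expected(0.7, 0.3))
        for p in (0.5, 0.6, 0.8, 0.9):
            assert composite_loglik(obs, _two_cell_expected(p, 1 - p)) < best

    def test_dimension_mismatch_rejected(self):
        obs = _two_cell_obs(1, 1)
        with pytest.raises(ValueError):
            composite_loglik(obs, JointSFS(np.ones((3, 3)) / 9))

    def test_zero_cells_floored_not_fatal(self):
        obs = _two_cell_obs(3, 1)
        exp = _two_cell_expected(1.0, 0.0)
        exp.n_reps = 1000
        val = composite_loglik(obs, exp)
        assert np.isfinite(val)

    def test_pooling_preserves_well_populated_cells(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(5, 50, size=(5, 5)).astype(float)
        obs = JointSFS(counts)
        p = rng.random((5, 5))
        mask = obs.segregating_mask()
        p[~mask] = 0
        exp = JointSFS(p / p.sum())
        assert composite_loglik(obs, exp, pool_below=3.0) == pytest.approx(
            composite_loglik(obs, exp, pool_below=0.0))


class TestModelSelect:
    @staticmethod
    def _fit(scenario, lnl, k, obs_hash="same"):
        return FitResult(scenario=scenario, params={}, max_lnl=lnl, k=k,
                         n_restarts=1, convergence_trace=[], converged=True,
                         obs_hash=obs_hash, seed=0)

    def test_equal_likelihood_prefers_fewer_parameters(self):
        ranked = model_select([self._fit("CON", -100.0, 6),
                               self._fit("DIV", -100.0, 4)])
        assert ranked[0].scenario == "DIV"
        assert ranked[1].delta_aic == pytest.approx(4.0)

    def test_waic_arithmetic_and_normalisation(self):
        ranked = model_select([self._fit("DIV", -10.0, 3),
                               self._fit("DIV_M", -10.0, 4)])
        # delta = (0, 2) -> weights (0.731, 0.269)
        assert ranked[0].waic == pytest.approx(0.7310586, rel=1e-5)
        assert ranked[1].waic == pytest.approx(0.2689414, rel=1e-5)
        assert sum(f.waic for f in ranked) == pytest.approx(1.0)

    def test_rank_invariant_under_constant_lnl_shift(self):
        fits1 = [self._fit("DIV", -50.0, 3), self._fit("CON", -48.0, 7),
                 self._fit("DIV_M", -49.0, 5)]
        fits2 = [self._fit("DIV", -550.0, 3), self._fit("CON", -548.0, 7),
                 self._fit("DIV_M", -549.0, 5)]
        r1 = [f.scenario for f in model_select(fits1)]
        r2 = [f.scenario for f in model_select(fits2)]
        assert r1 == r2
        d1 = [f.delta_aic for f in model_select(fits1)]
        d2 = [f.delta_aic for f in model_select(fits2)]
        assert d1 == pytest.approx(d2)

    def test_single_fit_and_mismatched_obs_rejected(self):
        with pytest.raises(ValueError):
            model_select([self._fit("DIV", -1.0, 3)])
        with pytest.raises(ValueError):
            model_select([self._fit("DIV", -1.0, 3),
                          self._fit("CON", -1.0, 6, obs_hash="other")])


def _quick_obs(model, n_chrom, n_snps, seed):
    sfs, length = simulate_sfs_counts(model, n_chrom, n_chrom, n_snps,
                                      seed=seed, folded=False)
    return attach_monomorphic_mass(sfs, length).fold()


QUICK = dict(n_starts=2, n_cycles=4, reps_per_eval=3000, grid_points=5,
             refine_points=3, n_screen=10, polish_maxfev=100,
             profile_points=3, profile_maxfev=40)


class TestMaximize:
    def test_deterministic_under_fixed_seed(self):
        model = DemographicModel("DIV", 800, 1200, 4000)
        obs = _quick_obs(model, 10, 400, seed=3)
        ranges = SearchRanges.default(n_low=200, n_high=5000)
        f1 = maximize(obs, "DIV", ranges, FitSettings(seed=5, **QUICK))
        f2 = maximize(obs, "DIV", ranges, FitSettings(seed=5, **QUICK))
        assert f1.params == f2.params
        assert f1.max_lnl == f2.max_lnl

    def test_result_respects_search_ranges(self):
        model = DemographicModel("DIV_M", 800, 1200, 4000,
                                 m_smo_to_chd=1e-5, m_chd_to_smo=1e-5)
        obs = _quick_obs(model, 10, 300, seed=4)
        ranges = SearchRanges.default(n_low=300, n_high=3000)
        fit = maximize(obs, "DIV_M", ranges, FitSettings(seed=1, **QUICK))
        for name, value in fit.params.items():
            lo, hi, _ = ranges[name]
            assert lo <= value <= hi

    def test_near_point_ranges_return_that_point(self):
        model = DemographicModel("DIV", 1000, 1000, 5000)
        obs = _quick_obs(model, 8, 200, seed=6)
        ranges = SearchRanges({
            "n_smo": (999.0, 1001.0, "uniform"),
            "n_chd": (999.0, 1001.0, "uniform"),
            "t_div": (4999.0, 5001.0, "uniform"),
        })
        fit = maximize(obs, "DIV", ranges,
                       FitSettings(seed=2, n_starts=1, n_cycles=1,
                                   reps_per_eval=1000, polish=False,
                                   n_screen=0))
        assert fit.params["n_smo"] == pytest.approx(1000, abs=1.1)
        assert fit.params["t_div"] == pytest.approx(5000, abs=1.1)

    @pytest.mark.parametrize("seed", [21, 22])
    def test_divergence_parameter_recovery(self, seed):
        """DIV truth refits land within 30% of the generating sizes and
        divergence time at desk scale (1200 SNPs, 20+20 chromosomes)."""
        truth = DemographicModel("DIV", n_smo=1500, n_chd=2500, t_div=10_000)
        obs = _quick_obs(truth, 20, 1200, seed=seed)
        ranges = SearchRanges.default(n_low=100, n_high=10_000).updated(
            t_div=(275.0, 60_000.0, "uniform"))
        fit = maximize(obs, "DIV", ranges,
                       FitSettings(seed=seed, n_starts=2, n_cycles=4,
                                   reps_per_eval=6000, n_screen=15,
                                   polish_maxfev=120, profile_points=5,
                                   profile_maxfev=60))
        assert fit.params["n_smo"] == pytest.approx(1500, rel=0.3)
        assert fit.params["n_chd"] == pytest.approx(2500, rel=0.3)
        assert fit.params["t_div"] == pytest.approx(10_000, rel=0.3)

    def test_no_spurious_migration_support_on_divergence_truth(self):
        """Fitting DIV_M to data generated without migration should not
        beat DIV by more than the AIC penalty margin."""
        truth = DemographicModel("DIV", n_smo=1500, n_chd=2500, t_div=10_000)
        obs = _quick_obs(truth, 16, 800, seed=31)
        ranges = SearchRanges.default(n_low=100, n_high=10_000).updated(
            t_div=(275.0, 60_000.0, "uniform"))
        settings = FitSettings(seed=31, n_starts=2, n_cycles=3,
                               reps_per_eval=5000, n_screen=10,
                               polish_maxfev=100, profile_points=3,
                               profile_maxfev=40)
        fit_div = maximize(obs, "DIV", ranges, settings)
        fit_divm = maximize(obs, "DIV_M", ranges, settings)
        ranked = model_select([fit_div, fit_divm])
        aic = {f.scenario: f.aic for f in ranked}
        assert aic["DIV"] - aic["DIV_M"] <= 2.0


class TestParametricBootstrap:
    def test_smoke_two_replicates(self):
        truth = DemographicModel("DIV", 1000, 1500, 6000)
        ranges = SearchRanges.default(n_low=200, n_high=6000).updated(
            t_div=(275.0, 30_000.0, "uniform"))
        settings = FitSettings(seed=41, n_starts=1, n_cycles=2,
                               reps_per_eval=1500, grid_points=5,
                               refine_points=0, n_screen=5, polish=False,
                               profile_points=0)
        res = parametric_bootstrap(truth, 10, 10, 200, 2, ranges, settings)
        assert isinstance(res, BootstrapResult)
        assert res.n_requested == 2
        for name in ("n_smo", "n_chd", "t_div"):
            assert len(res.replicates[name]) == res.n_converged
            lo, hi = res.ci[name]
            assert lo <= hi

    def test_percentile_interval_covers_truth_at_moderate_scale(self):
        truth = DemographicModel("DIV", 1500, 1500, 8000)
        ranges = SearchRanges.default(n_low=200, n_high=8000).updated(
            t_div=(275.0, 40_000.0, "uniform"))
        settings = FitSettings(seed=43, n_starts=1, n_cycles=3,
                               reps_per_eval=3000, grid_points=5,
                               refine_points=3, n_screen=8,
                               polish_maxfev=60, profile_points=0)
        res = parametric_bootstrap(truth, 12, 12, 500, 6, ranges, settings)
        lo, hi = res.ci["t_div"]
        assert lo <= truth.t_div <= hi
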