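import numpy as np
import pytest
from scipy import stats

import adexpr as ax
from adexpr.adequacy import (STAT_NAMES, adequacy_pvalues, observed_stats,
                             simulate_null, stat_slope)
from adexpr.contrasts import ContrastSet
from adexpr.models import ModelParams

from conftest import make_traits


def contrast_set(pics, v_exp=None, xhat=None, height=None):
    pics = np.asarray(pics, float)
    n = len(pics)
    return ContrastSet(
        pic=pics,
        v_exp=np.ones(n) if v_exp is None else np.asarray(v_exp, float),
        xhat=np.zeros(n) if xhat is None else np.asarray(xhat, float),
        height=np.arange(n, dtype=float) if height is None
        else np.asarray(height, float),
        xroot=0.0, v_root=1.0)


class TestStatistics:
    def test_cvar_no_variation(self):
        assert ax.stat_cvar(contrast_set([1.0, -1.0, 1.0])) == pytest.approx(0.0)

    def test_cvar_two_values(self):
        # |pics| {1, 3}: sample sd sqrt(2), mean 2
        assert ax.stat_cvar(contrast_set([1.0, -3.0])) == pytest.approx(
            np.sqrt(2) / 2)

    def test_cvar_all_zero_is_na(self):
        assert np.isnan(ax.stat_cvar(contrast_set([0.0, 0.0, 0.0])))

    def test_dcdf_single_zero(self):
        assert ax.stat_dcdf(contrast_set([0.0])) == pytest.approx(0.5)

    def test_dcdf_normal_quantiles_small(self):
        q = stats.norm.ppf(np.arange(1, 20) / 20)
        assert ax.stat_dcdf(contrast_set(q)) <= 0.05 + 1 / 19

    def test_dcdf_far_tail_near_one(self):
        d = ax.stat_dcdf(contrast_set([10.0, 11.0, 12.0]))
        assert d == pytest.approx(1.0, abs=1e-6)

    def test_dcdf_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        assert ax.stat_dcdf(contrast_set(x)) == pytest.approx(
            stats.kstest(x, "norm").statistic, abs=1e-12)

    @pytest.mark.parametrize("x,y,expected", [
        ([0.0, 1.0], [1.0, 2.0], 1.0),
        ([1.0, 2.0, 3.0], [2.0, 4.0, 6.0], 2.0)])
    def test_slope_examples(self, x, y, expected):
        assert stat_slope(x, y) == pytest.approx(expected)

    def test_slope_constant_predictor_is_na(self):
        assert np.isnan(stat_slope([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))

    def test_slope_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            stat_slope([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_observed_stats_bindings(self):
        """s.asr, s.hgt, s.var regress |pic| on x̂, height, v_exp."""
        cs = contrast_set([1.0, -2.0, 3.0], v_exp=[1.0, 2.0, 3.0],
                          xhat=[0.0, 1.0, 2.0], height=[2.0, 1.0, 0.0])
        obs = observed_stats(cs)
        y = np.abs(cs.pic)
        assert obs["s.asr"] == pytest.approx(stat_slope(cs.xhat, y))
        assert obs["s.hgt"] == pytest.approx(stat_slope(cs.height, y))
        assert obs["s.var"] == pytest.approx(stat_slope(cs.v_exp, y))


class TestPvalues:
    def null_of(self, draws):
        return {s: np.asarray(draws, float) for s in STAT_NAMES}

    def obs_of(self, v):
        return {s: float(v) for s in STAT_NAMES}

    def test_observed_above_all_draws(self):
        null = self.null_of(np.linspace(0, 1, 999))
        res = adequacy_pvalues(self.obs_of(2.0), null, n_sim=999)
        assert res.pvalues["c.var"] == pytest.approx(0.002)

    def test_observed_at_null_median_capped_at_one(self):
        null = self.null_of(np.arange(999, dtype=float))
        res = adequacy_pvalues(self.obs_of(499.0), null, n_sim=999)
        assert res.pvalues["c.var"] == 1.0

    def test_na_observed_gives_na_p(self):
        null = self.null_of(np.linspace(0, 1, 200))
        obs = self.obs_of(0.5)
        obs["s.hgt"] = np.nan
        res = adequacy_pvalues(obs, null, n_sim=200)
        assert np.isnan(res.pvalues["s.hgt"])
        assert not np.isnan(res.pvalues["c.var"])

    def test_all_null_na_warns_and_gives_na(self):
        null = self.null_of(np.linspace(0, 1, 200))
        null["s.hgt"] = np.full(200, np.nan)
        with pytest.warns(UserWarning, match="s.hgt"):
            res = adequacy_pvalues(self.obs_of(0.5), null, n_sim=200)
        assert np.isnan(res.pvalues["s.hgt"])

    def test_na_excluded_from_adequacy_verdict(self):
        null = self.null_of(np.linspace(0, 1, 200))
        obs = self.obs_of(0.5)
        obs["s.hgt"] = np.nan
        res = adequacy_pvalues(obs, null, n_sim=200)
        assert res.adequate() is True
        all_na = {s: np.nan for s in STAT_NAMES}
        assert adequacy_pvalues(all_na, null, n_sim=200).adequate() is None


class TestSimulateNull:
    def utree(self, alpha=0.0, seed=5):
        tree = ax.simulate_tree(12, 1.0, seed=seed)
        model = "OU" if alpha else "BM"
        return ax.rescale_to_unit_tree(
            tree, ModelParams(model=model, sigsq=1.0, alpha=alpha))

    def test_too_few_simulations_error(self):
        with pytest.raises(ValueError, match="n_sim"):
            simulate_null(self.utree(), n_sim=50)

    def test_deterministic_given_seed(self):
        u = self.utree()
        a = simulate_null(u, n_sim=200, seed=3)
        b = simulate_null(u, n_sim=200, seed=3)
        for s in STAT_NAMES:
            assert np.array_equal(a[s], b[s], equal_nan=True)

    def test_mean_consistent_across_seeds(self):
        """Two independent seeds agree on the c.var null mean to 3 MC SEs."""
        u = self.utree()
        a = simulate_null(u, n_sim=1000, seed=1)["c.var"]
        b = simulate_null(u, n_sim=1000, seed=2)["c.var"]
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_huge_alpha_makes_shgt_na(self):
        """Strong pull leaves ~no node-height variance on the unit tree."""
        u = self.utree(alpha=300.0)
        draws = simulate_null(u, n_sim=200, seed=0)
        assert np.isnan(draws["s.hgt"]).mean() >= 0.99
        tv = ax.simulate_traits(u.tree, ModelParams(model="BM", sigsq=1.0),
                                seed=1)
        obs = observed_stats(ax.compute_pics(u, tv))
        assert np.isnan(obs["s.hgt"])

    def test_adequacy_result_bitwise_deterministic(self):
        tree = ax.simulate_tree(10, 1.0, seed=2)
        tv = ax.simulate_traits(tree, ModelParams(model="BM", sigsq=1.0), seed=4)
        f = ax.fit_model(tree, tv, "BM")
        r1 = f.adequacy(n_sim=200, seed=9)
        r2 = f.adequacy(n_sim=200, seed=9)
        assert r1.pvalues == r2.pvalues
        for s in STAT_NAMES:
            assert np.array_equal(r1.null[s], r2.null[s], equal_nan=True)
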