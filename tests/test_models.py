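import math

import numpy as np
import pandas as pd
import pytest

import adexpr as ax
from adexpr.models import ModelParams, PhyloTraitModel

from conftest import make_traits, mvn_loglik_bruteforce


class TestLoglik:
    def test_bm_closed_form_two_tips(self, two_tip, two_tip_traits):
        p = ModelParams(model="BM", sigsq=1.0, z0=1.0)
        ll = ax.model_loglik(two_tip, two_tip_traits, p)
        assert ll == pytest.approx(-math.log(2 * math.pi) - 1, abs=1e-12)

    def test_ou_and_eb_limits_match_bm(self, two_tip, two_tip_traits):
        bm = ax.model_loglik(two_tip, two_tip_traits,
                             ModelParams(model="BM", sigsq=1.0, z0=1.0))
        ou = ax.model_loglik(two_tip, two_tip_traits,
                             ModelParams(model="OU", sigsq=1.0, alpha=1e-12, z0=1.0))
        eb = ax.model_loglik(two_tip, two_tip_traits,
                             ModelParams(model="EB", sigsq=1.0, r=1e-12, z0=1.0))
        assert ou == pytest.approx(bm, abs=1e-6)
        assert eb == pytest.approx(bm, abs=1e-6)

    @pytest.mark.parametrize("model,extra", [
        ("BM", {}), ("OU", {"alpha": 1.3}), ("EB", {"r": 0.8})])
    def test_matches_bruteforce_mvn_with_se(self, model, extra):
        """Contrasts-path likelihood equals the dense-covariance density."""
        rng = np.random.default_rng(42)
        for seed in range(20):
            tree = ax.simulate_tree(rng.integers(3, 9), height=1.0, seed=seed)
            labs = tree.tip_labels
            tv = make_traits(dict(zip(labs, rng.normal(size=len(labs)))),
                             se=pd.Series(rng.uniform(0, 0.4, len(labs)),
                                          index=labs))
            p = ModelParams(model=model, sigsq=float(rng.uniform(0.3, 3.0)),
                            z0=float(rng.normal()), **extra)
            assert ax.model_loglik(tree, tv, p) == pytest.approx(
                mvn_loglik_bruteforce(tree, tv, p), abs=1e-8)

    def test_matches_bruteforce_with_root_edge(self, three_tip):
        """A pruned tree's stem contributes shared variance correctly."""
        sub = ax.prune_tips(three_tip, {"A", "B"})
        assert sub.root_edge > 0
        tv = make_traits({"A": 0.3, "B": -0.9}, se=0.1)
        p = ModelParams(model="BM", sigsq=1.4, z0=0.2)
        assert ax.model_loglik(sub, tv, p) == pytest.approx(
            mvn_loglik_bruteforce(sub, tv, p), abs=1e-10)

    def test_nonultrametric_ou_errors(self):
        t = ax.parse_newick("((A:1,B:2):1,C:2);")
        tv = make_traits({"A": 0.0, "B": 1.0, "C": 2.0})
        with pytest.raises(ValueError, match="ultrametric"):
            ax.model_loglik(t, tv, ModelParams(model="OU", sigsq=1.0, alpha=1.0))

    def test_singular_covariance_errors(self):
        t = ax.parse_newick("(A:0,B:0);")
        tv = make_traits({"A": 0.0, "B": 1.0})
        with pytest.raises(ValueError, match="singular"):
            ax.model_loglik(t, tv, ModelParams(model="BM", sigsq=1.0))


class TestFit:
    def test_bm_two_tip_analytic_optimum(self, two_tip, two_tip_traits):
        f = ax.fit_model(two_tip, two_tip_traits, "BM")
        assert f.params.sigsq == pytest.approx(1.0, rel=1e-6)
        assert f.params.z0 == pytest.approx(1.0, abs=1e-9)
        assert f.aic == pytest.approx(2 * 2 - 2 * f.lnL)
        assert f.k == 2

    def test_constant_trait_hits_boundary(self, three_tip):
        tv = make_traits({"A": 1.0, "B": 1.0, "C": 1.0})
        f = ax.fit_model(three_tip, tv, "BM")
        assert not f.converged
        assert "sigsq at search bound" in f.notes
        assert f.params.sigsq <= 1e-7

    def test_se_monotonicity_on_bm_fits(self):
        """Adding measurement error never inflates the fitted rate (median)."""
        tree = ax.simulate_tree(30, 1.0, seed=8)
        diffs = []
        for i in range(20):
            tv0 = ax.simulate_traits(tree, ModelParams(model="BM", sigsq=1.5),
                                     seed=100 + i)
            tv1 = ax.TraitVector(tv0.values,
                                 pd.Series(0.5, index=tv0.values.index))
            s0 = ax.fit_model(tree, tv0, "BM").params.sigsq
            s1 = ax.fit_model(tree, tv1, "BM").params.sigsq
            diffs.append(s1 - s0)
        assert np.median(diffs) < 0

    def test_bm_rate_recovery_smoke(self):
        tree = ax.simulate_tree(100, 1.0, seed=3)
        ratios = [ax.fit_model(
            tree, ax.simulate_traits(tree, ModelParams(model="BM", sigsq=2.0),
                                     seed=i), "BM").params.sigsq / 2.0
            for i in range(20)]
        assert 0.8 < np.median(ratios) < 1.2

    def test_fit_deterministic_given_seed(self):
        tree = ax.simulate_tree(15, 1.0, seed=4)
        tv = ax.simulate_traits(tree, ModelParams(model="OU", sigsq=1.0,
                                                  alpha=2.0), seed=9)
        f1 = ax.fit_model(tree, tv, "OU", seed=5)
        f2 = ax.fit_model(tree, tv, "OU", seed=5)
        assert f1.params == f2.params and f1.lnL == f2.lnL

    def test_results_summary_mentions_model(self, two_tip, two_tip_traits):
        model = PhyloTraitModel(two_tip, two_tip_traits, model="BM")
        s = model.fit().summary()
        assert "BM" in s and "AIC" in s


class TestCompare:
    def _fit_pair(self, aics):
        tree = ax.simulate_tree(8, 1.0, seed=1)
        tv = ax.simulate_traits(tree, ModelParams(model="BM", sigsq=1.0), seed=2)
        fits = []
        for m, aic in aics.items():
            f = ax.fit_model(tree, tv, m)
            f.aic = aic
            f.lnL = (2 * f.k - aic) / 2
            fits.append(f)
        return fits

    def test_akaike_weights(self):
        fits = self._fit_pair({"BM": 10.0, "OU": 12.0})
        cmp = ax.compare_models(fits)
        assert cmp.best == "BM"
        assert cmp.weights["BM"] == pytest.approx(0.7311, abs=1e-4)
        assert cmp.weights["OU"] == pytest.approx(0.2689, abs=1e-4)
        assert sum(cmp.weights.values()) == pytest.approx(1.0)
        assert cmp.delta_aic["BM"] == 0.0

    def test_tie_broken_toward_fewer_parameters(self):
        cmp = ax.compare_models(self._fit_pair({"BM": 10.0, "OU": 10.0}))
        assert cmp.best == "BM"

    def test_tie_broken_by_fixed_order(self):
        cmp = ax.compare_models(self._fit_pair({"EB": 10.0, "OU": 10.0}))
        assert cmp.best == "EB"

    def test_single_fit_errors(self):
        fits = self._fit_pair({"BM": 10.0})
        with pytest.raises(ValueError, match="at least 2"):
            ax.compare_models(fits)

    def test_different_data_errors(self):
        tree = ax.simulate_tree(8, 1.0, seed=1)
        tv1 = ax.simulate_traits(tree, ModelParams(model="BM", sigsq=1.0), seed=2)
        tv2 = ax.simulate_traits(tree, ModelParams(model="BM", sigsq=1.0), seed=3)
        f1 = ax.fit_model(tree, tv1, "BM")
        f2 = ax.fit_model(tree, tv2, "OU")
        with pytest.raises(ValueError, match="same data"):
            ax.compare_models([f1, f2])
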