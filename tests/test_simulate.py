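import numpy as np
import pandas as pd
import pytest

import adexpr as ax
from adexpr.models import ModelParams
from adexpr.simulate import SimulationConfig, mark_clade, simulate_dataset


class TestSimulateTree:
    def test_two_tips_forced_topology(self):
        t = ax.simulate_tree(2, height=3.0, seed=0)
        assert t.n_tips == 2
        assert np.allclose(t.depths()[t.tip_indices], 3.0)

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_ultrametric_at_exact_height(self, seed):
        t = ax.simulate_tree(20, height=2.5, seed=seed)
        assert ax.is_ultrametric(t, rel_tol=1e-9)
        assert t.height == pytest.approx(2.5, rel=1e-12)
        assert t.is_binary()

    def test_seed_contract(self):
        a = ax.simulate_tree(20, 1.0, seed=1)
        b = ax.simulate_tree(20, 1.0, seed=2)
        assert a.to_newick() != b.to_newick()
        assert a.height == pytest.approx(b.height)
        assert ax.simulate_tree(20, 1.0, seed=1).to_newick() == a.to_newick()

    def test_too_few_tips_errors(self):
        with pytest.raises(ValueError):
            ax.simulate_tree(1, 1.0, seed=0)


class TestSimulateTraits:
    def test_vanishing_rate_pins_tips_to_root(self):
        tree = ax.simulate_tree(10, 1.0, seed=4)
        tv = ax.simulate_traits(tree, ModelParams(model="BM", sigsq=1e-12,
                                                  z0=3.0), seed=0)
        assert np.allclose(tv.values.to_numpy(), 3.0, atol=1e-4)

    def test_bm_divergence_variance_monte_carlo(self):
        """Var(x_A - x_B) = 2 sigma^2 T on a 2-tip tree."""
        tree = ax.parse_newick("(A:1,B:1);")
        p = ModelParams(model="BM", sigsq=2.0)
        d = np.array([(lambda v: v["A"] - v["B"])(
            ax.simulate_traits(tree, p, seed=i).values) for i in range(10000)])
        assert 3.8 < d.var(ddof=1) < 4.2

    def test_strong_ou_decorrelates_nonsister_tips(self):
        tree = ax.parse_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
        p = ModelParams(model="OU", sigsq=2.0, alpha=20.0)
        xs = np.array([[ax.simulate_traits(tree, p, seed=i).values[k]
                        for k in ("A", "C")] for i in range(10000)])
        cov = np.cov(xs[:, 0], xs[:, 1])[0, 1]
        assert -0.02 < cov < 0.02

    def test_eb_variance_concentrates_near_root(self):
        """EB tip variance matches its closed form (Monte Carlo, 3 SEs)."""
        tree = ax.parse_newick("(A:1,B:1);")
        r, s2 = 2.0, 1.5
        p = ModelParams(model="EB", sigsq=s2, r=r)
        x = np.array([ax.simulate_traits(tree, p, seed=i).values["A"]
                      for i in range(10000)])
        expect = s2 * (1 - np.exp(-r)) / r
        mc_se = expect * np.sqrt(2 / 10000)
        assert abs(x.var(ddof=1) - expect) < 3 * mc_se


class TestSimulateDataset:
    def test_zero_noise_replicates_equal_trait(self):
        cfg = SimulationConfig(n_tips=8, n_genes=5, noise_sd=0.0,
                               n_replicates=3, seed=3)
        tree, expr, truth = simulate_dataset(cfg)
        tv = ax.summarize_replicates(expr, expr.genes[0])
        assert (tv.se == 0).all()
        # replicates within a species are identical
        v = expr.values.iloc[0]
        for sp in tree.tip_labels:
            reps = v[[c for c in expr.samples if c.startswith(sp + "_")]]
            assert reps.nunique() == 1

    def test_fixed_seed_bitwise_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(n_tips=6, n_genes=4, seed=11)
        p1 = ax.write_dataset(*simulate_dataset(cfg), tmp_path / "a")
        p2 = ax.write_dataset(*simulate_dataset(cfg), tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()

    def test_truth_table_records_generating_models(self):
        cfg = SimulationConfig(n_tips=8, n_genes=30, seed=2,
                               model_weights={"BM": 0.5, "OU-shift": 0.5})
        _, expr, truth = simulate_dataset(cfg)
        assert set(truth["model"]) <= {"BM", "OU-shift"}
        shifted = truth[truth["model"] == "OU-shift"]
        assert (shifted["clade_tips"] != "").all()
        assert list(truth.index) == list(expr.genes)

    def test_two_rate_clade_has_inflated_divergence(self):
        """The marked clade diverges faster under BM-2rate."""
        cfg = SimulationConfig(n_tips=12, n_genes=1, seed=5,
                               model_weights={"BM-2rate": 1.0},
                               rate_factor=64.0, noise_sd=0.0, n_replicates=1)
        tree, _, truth = simulate_dataset(cfg)
        clade = set(truth["clade_tips"].iloc[0].split(","))
        outside = [t for t in tree.tip_labels if t not in clade]
        spread_in, spread_out = [], []
        for g in range(150):
            cfg2 = SimulationConfig(**{**cfg.__dict__, "seed": 100 + g})
            _, expr, _ = simulate_dataset(cfg2, tree=tree)
            tv = ax.summarize_replicates(expr, expr.genes[0])
            spread_in.append(tv.values[sorted(clade)].var())
            spread_out.append(tv.values[outside].var())
        assert np.mean(spread_in) > 4 * np.mean(spread_out)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_tips=3)
        with pytest.raises(ValueError):
            SimulationConfig(model_weights={"nope": 1.0})
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-0.1)


class TestMarkClade:
    def test_clade_size_near_target(self):
        tree = ax.simulate_tree(30, 1.0, seed=8)
        mask = mark_clade(tree, target_frac=1 / 3)
        n_tips_in = sum(mask[i] for i in tree.tip_indices)
        assert 4 <= n_tips_in <= 16
        # the mask is a connected clade: every masked non-root node has a
        # masked parent or is the clade stem
        stems = [i for i in range(tree.n_nodes)
                 if mask[i] and not mask[tree.parent[i]]]
        assert len(stems) == 1
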