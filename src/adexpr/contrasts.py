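"""Felsenstein pruning: independent contrasts, likelihood, and BM simulation.

The :class:`PruningEngine` precomputes the pruning recursion's structural
coefficients for one tree + branch-length vector, then evaluates contrasts,
the BM log-likelihood, and BM(σ=1) simulations as (mostly) vectorized array
operations.  All three consumers — model fitting, observed test statistics,
and the parametric-bootstrap null — go through the same engine, so observed
and simulated data share one code path by construction.

At a node with children carrying values (x_a, v_a) and (x_b, v_b), where v
is the child's branch length plus its accumulated extension:

    pic  = (x_a − x_b) / √(v_a + v_b)
    x̂    = (v_b·x_a + v_a·x_b) / (v_a + v_b)
    the parent branch is extended by v_a·v_b / (v_a + v_b)

On a unit tree (branch lengths = model variance) the pics are i.i.d.
N(0, 1) when the fitted model is the generating one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tree import Phylogeny, phylo_vcv

#: unit-tree branch lengths below this are floored before PIC division
LENGTH_FLOOR = 1e-12


class PolytomyError(ValueError):
    """Tree is not strictly bifurcating; run resolve_polytomies first."""


def _topology(tree: Phylogeny):
    """Cached structural arrays for the pruning recursion (binary trees)."""
    cached = getattr(tree, "_topo_cache", None)
    if cached is not None:
        return cached
    int_nodes, child_a, child_b = [], [], []
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            continue
        if len(kids) != 2:
            raise PolytomyError(
                "pruning requires a strictly bifurcating tree; "
                "apply resolve_polytomies() first")
        int_nodes.append(node)
        child_a.append(kids[0])
        child_b.append(kids[1])
    cache = (np.array(int_nodes, dtype=np.intp),
             np.array(child_a, dtype=np.intp),
             np.array(child_b, dtype=np.intp))
    tree._topo_cache = cache
    return cache


class PruningEngine:
    """Pruning coefficients for a fixed tree and branch-length vector.

    Parameters
    ----------
    tree : Phylogeny
        Bifurcating tree supplying the topology (and tip order).
    lengths : array, optional
        Branch-length vector replacing ``tree.length`` (same node
        indexing); used by model fitting to re-evaluate transforms on a
        fixed topology without rebuilding trees.
    """

    def __init__(self, tree: Phylogeny, lengths: np.ndarray | None = None):
        self.tree = tree
        self.int_nodes, self.child_a, self.child_b = _topology(tree)
        raw = tree.length if lengths is None else np.asarray(lengths, float)
        self.raw_lengths = raw
        self.lengths = np.maximum(raw, LENGTH_FLOOR)
        self.lengths[tree.root] = raw[tree.root]  # a stem of 0 means "absent"

        # structural pass: effective child variances and extensions
        ext = np.zeros(tree.n_nodes)
        va = np.empty(len(self.int_nodes))
        vb = np.empty(len(self.int_nodes))
        for k in range(len(self.int_nodes)):
            a, b = self.child_a[k], self.child_b[k]
            va[k] = self.lengths[a] + ext[a]
            vb[k] = self.lengths[b] + ext[b]
            ext[self.int_nodes[k]] = va[k] * vb[k] / (va[k] + vb[k])
        self.v_a, self.v_b = va, vb
        self.v_exp = va + vb
        self.v_root = float(ext[tree.root] + self.lengths[tree.root])
        self.tip_order = tree.tip_indices
        self.tip_labels = [tree.labels[i] for i in self.tip_order]
        d = tree.depths(self.raw_lengths)
        self.node_heights = d[self.int_nodes]

    @property
    def n_contrasts(self) -> int:
        return len(self.int_nodes)

    def _check_values(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        one_d = values.ndim == 1
        if one_d:
            values = values[:, None]
        if values.shape[0] != len(self.tip_order):
            raise ValueError(
                f"expected {len(self.tip_order)} tip values, got {values.shape[0]}")
        return values

    def contrasts(self, values: np.ndarray):
        """Standardized contrasts and node estimates for tip data.

        ``values`` is (n_tips,) or (n_tips, m) in ``tip_labels`` order.
        Returns ``(pics, xhat, xroot)`` with shapes (n−1, m), (n−1, m),
        (m,); squeeze to 1-D yourself if m == 1.
        """
        values = self._check_values(values)
        m = values.shape[1]
        X = np.empty((self.tree.n_nodes, m))
        X[self.tip_order] = values
        for k in range(self.n_contrasts):
            a, b = self.child_a[k], self.child_b[k]
            X[self.int_nodes[k]] = (self.v_b[k] * X[a] + self.v_a[k] * X[b]) \
                / (self.v_a[k] + self.v_b[k])
        raw = X[self.child_a] - X[self.child_b]
        pics = raw / np.sqrt(self.v_exp)[:, None]
        return pics, X[self.int_nodes], X[self.tree.root]

    def loglik(self, values: np.ndarray, z0: float | None = None):
        """BM(σ=1) Gaussian log-likelihood of tip data on this tree.

        Exact multivariate-normal log-density with covariance given by
        shared branch lengths, factorized through the contrasts:

            lnL = Σ_k N(c_k; 0, v_k) + N(x̂_root; z0, v_root)

        with raw contrasts c_k.  ``z0=None`` profiles the root state at
        its GLS estimate x̂_root (the maximum-likelihood value).  Returns
        (lnL, ẑ0); vectorized over columns of ``values``.
        """
        values = self._check_values(values)
        pics, _, xroot = self.contrasts(values)
        ll = -0.5 * (np.log(2 * math.pi * self.v_exp).sum()
                     + (pics ** 2).sum(axis=0))
        ll -= 0.5 * math.log(2 * math.pi * self.v_root)
        if z0 is not None:
            ll -= 0.5 * (xroot - z0) ** 2 / self.v_root
        out = ll if values.shape[1] > 1 else float(ll[0])
        zhat = xroot if values.shape[1] > 1 else float(xroot[0])
        return out, zhat

    def simulate_bm(self, n_sim: int, rng: np.random.Generator) -> np.ndarray:
        """Simulate BM(σ=1) tip values from root state 0; (n_tips, n_sim)."""
        X = np.empty((self.tree.n_nodes, n_sim))
        sd = np.sqrt(self.raw_lengths)
        for node in self.tree.preorder:
            p = self.tree.parent[node]
            eps = rng.standard_normal(n_sim) * sd[node]
            X[node] = eps if p < 0 else X[p] + eps
        return X[self.tip_order]


@dataclass
class ContrastSet:
    """Phylogenetic independent contrasts with their node quantities.

    One entry per internal node (n_tips − 1 on a bifurcating tree):
    standardized contrast, expected variance (sum of effective child
    branch lengths), pruning ancestral estimate, and node height (depth
    from the root on the tree the contrasts were computed on).
    """

    pic: np.ndarray
    v_exp: np.ndarray
    xhat: np.ndarray
    height: np.ndarray
    xroot: float
    v_root: float

    def __len__(self) -> int:
        return len(self.pic)


def compute_pics(tree, traits) -> ContrastSet:
    """Independent contrasts of a trait vector on a (unit) tree.

    ``tree`` may be a :class:`~adexpr.tree.Phylogeny` or a
    :class:`~adexpr.unit_tree.UnitTree`; ``traits`` a TraitVector or a
    mapping species → value covering every tip.
    """
    phylo = getattr(tree, "tree", tree)
    engine = PruningEngine(phylo)
    values = _align_traits(traits, engine.tip_labels)
    pics, xhat, xroot = engine.contrasts(values)
    return ContrastSet(pic=pics[:, 0], v_exp=engine.v_exp, xhat=xhat[:, 0],
                       height=engine.node_heights, xroot=float(xroot[0]),
                       v_root=engine.v_root)


def _align_traits(traits, tip_labels: list[str]) -> np.ndarray:
    import pandas as pd

    inner = getattr(traits, "values", None)
    getter = inner if isinstance(inner, pd.Series) else traits
    missing = [t for t in tip_labels if t not in getter]
    if missing:
        raise KeyError(f"no trait value for tip(s): {missing}")
    return np.array([float(getter[t]) for t in tip_labels])


def blomberg_k(tree: Phylogeny, traits) -> float:
    """Blomberg's K statistic of phylogenetic signal (expectation 1 under BM).

    K = (MSE0/MSE)_observed / (MSE0/MSE)_expected with MSE0 the mean squared
    deviation from the phylogenetically (GLS) corrected mean, MSE the GLS
    mean squared error under the phylogenetic covariance C, and the
    expectation (tr C − n / Σ_ij (C⁻¹)_ij) / (n − 1).
    """
    labels, C = phylo_vcv(tree)
    n = len(labels)
    if n < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    x = _align_traits(traits, labels)
    if np.ptp(x) == 0:
        raise ValueError("Blomberg's K is undefined for a constant trait")
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    ahat = one @ Cinv @ x / (one @ Cinv @ one)
    resid = x - ahat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ Cinv @ resid / (n - 1)
    expected = (np.trace(C) - n / Cinv.sum()) / (n - 1)
    return float((mse0 / mse) / expected)
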