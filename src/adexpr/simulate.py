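"""Synthetic comparative expression data with known generating models.

Generates pure-birth ultrametric trees and gene × species log-expression
matrices evolved under BM, OU, or EB — plus the two misspecification
variants the adequacy statistics are meant to catch: a two-rate BM (σ²
multiplied on a marked clade) and a shifted-optimum OU (θ moved on a
marked clade).  Per-species replicates receive Gaussian noise on the log
scale, so collapsing them yields species means with honest standard
errors, mirroring how measurement error enters the phylogenetic models.

Every draw is controlled by a single seed through ``numpy`` SeedSequence
spawning: identical configurations give bitwise-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, TraitVector
from .tree import Phylogeny, write_newick
from .unit_tree import transform_lengths

GENE_MODELS = ("BM", "OU", "EB", "BM-2rate", "OU-shift")


def simulate_tree(n_tips: int, height: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule, rate 1) ultrametric tree scaled to exact height.

    Lineages split at exponential waiting times until ``n_tips`` are
    alive; all tips extend to the present, and branch lengths are then
    scaled so the root-to-tip depth is exactly ``height``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]  # time each node's branch starts
    labels: list[str | None] = [None, None, None]
    active = [1, 2]
    t = 0.0
    end_time = {}
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        end_time[node] = t
        for _ in range(2):
            parent.append(node)
            birth.append(t)
            labels.append(None)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / n_tips)
    lengths = np.zeros(len(parent))
    tip_no = 0
    for node in range(1, len(parent)):
        stop = end_time.get(node, t_end)
        lengths[node] = stop - birth[node]
        if node not in end_time:
            tip_no += 1
            labels[node] = f"t{tip_no}"
    lengths *= height / t_end
    return Phylogeny(parent, lengths, labels)


def _branch_variances(tree: Phylogeny, model: str, sigsq: float,
                      alpha: float, r: float,
                      rate_scale: np.ndarray | None = None) -> np.ndarray:
    """Per-branch *conditional* trait variances for recursive simulation.

    BM and EB are independent-increment processes, so the conditional
    variance over a branch equals its unit-tree variance increment.  OU is
    not: conditional on the parent, a branch of length b contributes
    (σ²/2α)(1 − e^{−2αb}) regardless of its position in the tree (the
    unit-tree increment instead discounts by the distance to the present).
    """
    from .models import ModelParams

    if model == "OU" and alpha > 0:
        base = (sigsq / (2 * alpha)) * (-np.expm1(-2 * alpha * tree.length))
        if tree.root_edge == 0.0:
            base = base.copy()
            base[tree.root] = 0.0
    else:
        base = transform_lengths(
            tree, ModelParams(model=model, sigsq=sigsq, alpha=alpha, r=r))
    if rate_scale is not None:
        base = base * rate_scale
    return base


def _simulate_on_tree(tree: Phylogeny, model: str, sigsq: float, alpha: float,
                      r: float, z0: float, rng: np.random.Generator,
                      rate_scale: np.ndarray | None = None,
                      theta_by_node: np.ndarray | None = None) -> pd.Series:
    """Recursive root→tip simulation of one trait on one tree.

    BM/EB draw Gaussian increments with the model's per-branch variance;
    OU pulls toward the branch's θ with weight e^{−αb} plus the
    conditional OU variance.  ``rate_scale`` multiplies branch variances
    (two-rate variants); ``theta_by_node`` gives each branch its optimum
    (shifted-optimum variants).
    """
    var = _branch_variances(tree, model, sigsq, alpha, r, rate_scale)
    x = np.empty(tree.n_nodes)
    for node in tree.preorder:
        p = tree.parent[node]
        anc = z0 if p < 0 else x[p]
        b = tree.length[node]
        if model == "OU" and alpha > 0:
            th = z0 if theta_by_node is None else theta_by_node[node]
            mean = th + (anc - th) * np.exp(-alpha * b)
        else:
            mean = anc
        x[node] = mean + rng.standard_normal() * np.sqrt(var[node])
    tips = tree.tip_indices
    return pd.Series({tree.labels[i]: x[i] for i in tips})


def simulate_traits(tree: Phylogeny, params, seed: int = 0) -> TraitVector:
    """Simulate one trait under ``params`` (a ModelParams); SE is 0.

    BM: child = parent + N(0, σ²·b).  OU: child = θ + (parent − θ)·e^{−αb}
    + N(0, (σ²/2α)(1 − e^{−2αb})).  EB: BM on EB-rescaled branch lengths.
    """
    rng = np.random.default_rng(seed)
    vals = _simulate_on_tree(tree, params.model, params.sigsq, params.alpha,
                             params.r, params.z0, rng,
                             theta_by_node=np.full(tree.n_nodes, params.theta))
    se = pd.Series(0.0, index=vals.index)
    return TraitVector(vals, se)


def mark_clade(tree: Phylogeny, target_frac: float = 1 / 3) -> np.ndarray:
    """Boolean mask over nodes for the clade whose tip count is closest to
    ``target_frac`` of the tips (ties to the first such node in postorder).
    The mask covers the clade's stem branch and everything below it."""
    n_desc = np.zeros(tree.n_nodes, dtype=int)
    for node in tree.postorder:
        n_desc[node] = 1 if tree.is_tip[node] else sum(
            n_desc[c] for c in tree.children[node])
    target = target_frac * tree.n_tips
    best, best_err = None, np.inf
    for node in tree.postorder:
        if tree.is_tip[node] or node == tree.root:
            continue
        err = abs(n_desc[node] - target)
        if err < best_err:
            best, best_err = node, err
    mask = np.zeros(tree.n_nodes, dtype=bool)

    def paint(node):
        mask[node] = True
        for c in tree.children[node]:
            paint(c)

    paint(best)
    return mask


@dataclass
class SimulationConfig:
    """Study-level settings for a synthetic comparative expression dataset.

    Defaults describe a modest bulk-RNA-seq comparative study: a 20-taxon
    ultrametric tree of unit height, a few hundred genes with evolutionary
    rates of order 1 on the log2-expression scale, OU constraint strengths
    αT in the range where OU and BM are distinguishable, triplicate
    sampling per species, and replicate noise of 0.2 log2 units.
    """

    n_tips: int = 20
    tree_height: float = 1.0
    n_genes: int = 200
    model_weights: dict = field(
        default_factory=lambda: {"BM": 1 / 3, "OU": 1 / 3, "EB": 1 / 3})
    sigsq_range: tuple = (0.5, 2.0)      # log-uniform
    alphaT_range: tuple = (1.0, 4.0)     # log-uniform, α = αT / T
    rT_range: tuple = (1.0, 3.0)         # uniform, r = rT / T
    z0: float = 0.0
    rate_factor: float = 8.0             # σ² multiplier on the clade (BM-2rate)
    theta_shift: float = 2.0             # optimum offset on the clade (OU-shift)
    clade_frac: float = 1 / 3
    n_replicates: int = 3
    noise_sd: float = 0.2                # per-replicate sd, log2 scale
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        bad = [m for m in self.model_weights if m not in GENE_MODELS]
        if bad:
            raise ValueError(f"unknown generating model(s): {bad}")
        if not all(w >= 0 for w in self.model_weights.values()) \
                or sum(self.model_weights.values()) <= 0:
            raise ValueError("model weights must be >= 0 and sum > 0")


def _draw_gene_params(cfg: SimulationConfig, rng: np.random.Generator):
    models = sorted(cfg.model_weights)
    w = np.array([cfg.model_weights[m] for m in models], float)
    name = models[rng.choice(len(models), p=w / w.sum())]
    lo, hi = cfg.sigsq_range
    sigsq = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    T = cfg.tree_height
    alpha = r = 0.0
    base = {"BM-2rate": "BM", "OU-shift": "OU"}.get(name, name)
    if base == "OU":
        lo, hi = cfg.alphaT_range
        alpha = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) / T
    if base == "EB":
        lo, hi = cfg.rT_range
        r = float(rng.uniform(lo, hi)) / T
    return name, base, sigsq, alpha, r


def simulate_dataset(cfg: SimulationConfig, tree: Phylogeny | None = None):
    """Simulate a full study: tree, log expression matrix, truth table.

    Returns ``(tree, ExpressionMatrix[log], truth)`` where truth is a
    DataFrame recording each gene's generating model, parameters, and (for
    the clade variants) the affected tips.  Replicate sample values are
    the simulated species trait plus N(0, noise_sd²); sample ids are
    ``<species>_r<j>``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    tree_seed, genes_seed = ss.spawn(2)
    if tree is None:
        tree = simulate_tree(cfg.n_tips, cfg.tree_height,
                             seed=tree_seed.generate_state(1)[0] & 0x7FFFFFFF)
    clade = mark_clade(tree, cfg.clade_frac)
    clade_tips = sorted(tree.labels[i] for i in tree.tip_indices if clade[i])

    gene_rngs = genes_seed.spawn(cfg.n_genes)
    species = tree.tip_labels
    sample_ids = [f"{sp}_r{j + 1}" for sp in species
                  for j in range(cfg.n_replicates)]
    data = np.empty((cfg.n_genes, len(sample_ids)))
    truth_rows = []
    width = len(str(cfg.n_genes))
    for g in range(cfg.n_genes):
        rng = np.random.default_rng(gene_rngs[g])
        name, base, sigsq, alpha, r = _draw_gene_params(cfg, rng)
        rate_scale = theta_by_node = None
        if name == "BM-2rate":
            rate_scale = np.where(clade, cfg.rate_factor, 1.0)
        if name == "OU-shift":
            theta_by_node = np.where(clade, cfg.z0 + cfg.theta_shift, cfg.z0)
        traits = _simulate_on_tree(tree, base, sigsq, alpha, r, cfg.z0, rng,
                                   rate_scale=rate_scale,
                                   theta_by_node=theta_by_node)
        reps = np.repeat(traits.reindex(species).to_numpy(), cfg.n_replicates)
        noise = rng.standard_normal(reps.size) * cfg.noise_sd
        data[g] = reps + noise
        truth_rows.append({
            "gene": f"g{g + 1:0{width}d}", "model": name, "sigsq": sigsq,
            "alpha": alpha, "r": r, "z0": cfg.z0,
            "clade_tips": ",".join(clade_tips) if name in
            ("BM-2rate", "OU-shift") else "",
        })
    genes = [row["gene"] for row in truth_rows]
    values = pd.DataFrame(data, index=genes, columns=sample_ids)
    sample_map = pd.DataFrame(
        {"species": np.repeat(species, cfg.n_replicates)},
        index=pd.Index(sample_ids, name="sample_id"))
    expr = ExpressionMatrix(values, sample_map, tag="log")
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return tree, expr, truth


def write_dataset(tree: Phylogeny, expr: ExpressionMatrix, truth: pd.DataFrame,
                  outdir) -> dict[str, Path]:
    """Write a simulated study in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_newick(tree, paths["tree"])
    expr.values.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    expr.sample_map.reset_index().to_csv(paths["samples"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t")
    return paths
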