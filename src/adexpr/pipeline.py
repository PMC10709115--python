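"""Per-gene analysis orchestration and study-level summaries.

For each gene (× tissue): collapse replicates to species means ± SE, prune
the tree to species with data, fit BM/OU/EB by maximum likelihood, pick
the lowest-AIC model, rescale to its unit tree, and test adequacy with the
five contrast statistics against a parametric-bootstrap null.  Genes are
analyzed independently; no multiple-testing correction is applied across
genes because each gene tests a single hypothesis (the data were generated
by its own fitted model).

Per-gene seeds are derived from the master seed by a stable hash of the
gene/tissue ids, so results are independent of gene order and reproducible
to the byte.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adequacy import STAT_NAMES, observed_stats, simulate_null, adequacy_pvalues
from .contrasts import compute_pics
from .expression import ExpressionMatrix, TraitVector, summarize_replicates
from .models import MODELS, ModelParams, compare_models, fit_model
from .tree import Phylogeny, prune_tips

MIN_TIPS_DEFAULT = 4


@dataclass
class AnalysisConfig:
    """Knobs of the per-gene analysis."""

    models: tuple = MODELS
    n_sim: int = 1000
    min_tips: int = MIN_TIPS_DEFAULT
    alpha: float = 0.05
    restarts: int = 3
    seed: int = 0
    log_offset: float = 1.0

    def as_dict(self) -> dict:
        return {"models": list(self.models), "n_sim": self.n_sim,
                "min_tips": self.min_tips, "alpha": self.alpha,
                "restarts": self.restarts, "seed": self.seed,
                "log_offset": self.log_offset}


@dataclass
class GeneResult:
    """Everything the study table records for one gene × tissue."""

    gene: str
    tissue: str | None
    n_tips: int
    skip_reason: str | None = None
    best_model: str | None = None
    delta_aic: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)
    params: ModelParams | None = None
    pvalues: dict = field(default_factory=dict)
    adequate: bool | None = None
    seed: int = 0

    def to_row(self) -> dict:
        row = {"gene": self.gene, "tissue": self.tissue if self.tissue is not None else "",
               "n_tips": self.n_tips,
               "skip_reason": self.skip_reason or "",
               "best_model": self.best_model or ""}
        for m in MODELS:
            row[f"daic_{m}"] = self.delta_aic.get(m, np.nan)
            row[f"w_{m}"] = self.weights.get(m, np.nan)
        p = self.params
        row.update({"sigsq": p.sigsq if p else np.nan,
                    "alpha": p.alpha if p else np.nan,
                    "r": p.r if p else np.nan,
                    "z0": p.z0 if p else np.nan})
        for s in STAT_NAMES:
            row[f"p_{s}"] = self.pvalues.get(s, np.nan)
        row["adequate"] = ("" if self.adequate is None
                           else str(bool(self.adequate)))
        row["seed"] = self.seed
        return row


def gene_seed(master_seed: int, gene: str, tissue: str | None = None) -> int:
    """Stable per-gene seed: crc32 of the ids folded with the master seed."""
    tag = f"{gene}|{tissue if tissue is not None else ''}"
    return (zlib.crc32(tag.encode()) ^ (master_seed * 0x9E3779B1)) & 0x7FFFFFFF


def run_gene(tree: Phylogeny, traits: TraitVector,
             cfg: AnalysisConfig | None = None,
             seed: int | None = None) -> GeneResult:
    """Full relative-fit + adequacy analysis of one gene.

    Prunes the tree to species with data; genes with fewer than
    ``cfg.min_tips`` species, zero trait variance, or total fit failure
    are skipped with a recorded reason rather than dropped silently.
    """
    cfg = cfg or AnalysisConfig()
    if seed is None:
        seed = cfg.seed
    shared = [t for t in tree.tip_labels if t in traits.values.index]
    res = GeneResult(gene=traits.gene, tissue=traits.tissue,
                     n_tips=len(shared), seed=seed)
    if len(shared) < cfg.min_tips:
        res.skip_reason = "too_few_tips"
        return res
    sub = prune_tips(tree, shared) if len(shared) < tree.n_tips else tree
    traits = traits.reorder(sub.tip_labels)
    if np.ptp(traits.values.to_numpy()) == 0:
        res.skip_reason = "zero_variance"
        return res

    fits, errors = [], []
    for m in cfg.models:
        try:
            fits.append(fit_model(sub, traits, m,
                                  restarts=cfg.restarts, seed=seed))
        except Exception as e:  # noqa: BLE001 - recorded, not swallowed
            errors.append(f"{m}: {e}")
    if not fits:
        res.skip_reason = "fit_failure"
        warnings.warn(f"all fits failed for {traits.gene}: {errors}")
        return res
    if len(fits) >= 2:
        cmp = compare_models(fits)
        best = cmp.best_fit
        res.delta_aic = cmp.delta_aic
        res.weights = cmp.weights
    else:
        best = fits[0]
        res.delta_aic = {best.model: 0.0}
        res.weights = {best.model: 1.0}
    res.best_model = best.model
    res.params = best.params

    utree = best.unit_tree()
    cs = compute_pics(utree, traits)
    obs = observed_stats(cs)
    null = simulate_null(utree, n_sim=cfg.n_sim, seed=seed)
    adq = adequacy_pvalues(obs, null, n_sim=cfg.n_sim, seed=seed)
    res.pvalues = adq.pvalues
    res.adequate = adq.adequate(cfg.alpha)
    return res


@dataclass
class StudyResult:
    """Per-gene table, recomputable summary, and run metadata."""

    genes: pd.DataFrame
    summary: pd.DataFrame
    metadata: dict

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"genes": outdir / "genes.tsv",
                 "summary": outdir / "summary.tsv",
                 "metadata": outdir / "run_metadata.yaml"}
        self.genes.to_csv(paths["genes"], sep="\t", index=False,
                          float_format="%.10g")
        self.summary.to_csv(paths["summary"], sep="\t", index=False,
                            float_format="%.10g")
        with open(paths["metadata"], "w") as fh:
            yaml.safe_dump(self.metadata, fh, sort_keys=True)
        return paths


def summarize_results(genes: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Study-level proportions, recomputed purely from the per-gene table."""
    rows = []
    analyzed = genes[genes["skip_reason"] == ""] if len(genes) else genes
    n_all, n = len(genes), len(analyzed)
    rows.append(("n_gene_tissue", n_all))
    rows.append(("n_analyzed", n))
    rows.append(("n_skipped", n_all - n))
    for m in MODELS:
        prop = (analyzed["best_model"] == m).mean() if n else np.nan
        rows.append((f"prop_best_{m}", prop))
    verdicts = analyzed["adequate"].replace("", np.nan).dropna() if n else []
    rows.append(("prop_adequate",
                 (pd.Series(verdicts) == "True").mean() if len(verdicts) else np.nan))
    for s in STAT_NAMES:
        p = analyzed[f"p_{s}"] if n else pd.Series(dtype=float)
        valid = p.dropna()
        rows.append((f"prop_inadequate_{s}",
                     (valid < alpha).mean() if len(valid) else np.nan))
    if n:
        rows.append(("n_na_s.hgt", int(analyzed["p_s.hgt"].isna().sum())))
    else:
        rows.append(("n_na_s.hgt", 0))
    return pd.DataFrame(rows, columns=["quantity", "value"])


def run_study(tree: Phylogeny | None, expr: ExpressionMatrix,
              cfg: AnalysisConfig | None = None,
              gene_trees: dict[str, Phylogeny] | None = None) -> StudyResult:
    """Analyze every gene × tissue combination of a study.

    ``tree`` is the species tree; per-gene trees, when supplied, override
    it (every gene id must then resolve to a tree).  Expression may be raw
    or normalized; anything not yet log-transformed is log2(x + offset)
    transformed first.  Deterministic given ``cfg.seed`` and independent
    of gene/sample ordering.
    """
    from .expression import log_transform

    cfg = cfg or AnalysisConfig()
    if len(expr.genes) == 0:
        raise ValueError("empty gene table")
    if expr.tag != "log":
        expr = log_transform(expr, offset=cfg.log_offset)
    if gene_trees is not None:
        missing = [g for g in expr.genes if g not in gene_trees]
        if missing:
            raise KeyError(f"no gene tree for gene(s): {missing[:10]}")
    elif tree is None:
        raise ValueError("need a species tree or per-gene trees")

    results = []
    for g in sorted(expr.genes):
        for tissue in expr.tissues():
            tv = summarize_replicates(expr, g, tissue)
            if len(tv) == 0:
                results.append(GeneResult(gene=g, tissue=tissue, n_tips=0,
                                          skip_reason="too_few_tips"))
                continue
            t = gene_trees[g] if gene_trees is not None else tree
            results.append(run_gene(t, tv, cfg,
                                    seed=gene_seed(cfg.seed, g, tissue)))
    genes = pd.DataFrame([r.to_row() for r in results])
    genes = genes.sort_values(["gene", "tissue"]).reset_index(drop=True)
    summary = summarize_results(genes, cfg.alpha)
    metadata = {
        "adexpr_version": __version__,
        "config": cfg.as_dict(),
        "n_gene_tissue": int(len(genes)),
        "tree_source": "per-gene trees" if gene_trees is not None
                       else "species tree",
        "polytomy_policy": "resolved to zero-length bifurcations upstream",
    }
    return StudyResult(genes=genes, summary=summary, metadata=metadata)
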