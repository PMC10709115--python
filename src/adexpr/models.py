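"""Maximum-likelihood fitting of BM, OU, and EB trait models with AIC.

Three single-regime Gaussian models of continuous trait evolution on a
phylogeny, each with a fixed per-tip measurement variance se² added to the
tip:

* **BM** — random walk, Δz̄ = σ·dW; among-lineage variance grows linearly
  at rate σ².
* **OU** — Δz̄ = −α(z̄ − θ) + σ·dW; a restoring force α pulls the trait
  toward an optimum θ, which this single-optimum parameterization
  constrains to equal the root state z0 (they are not separately
  identifiable from tip data on an ultrametric tree).
* **EB** — early burst: BM whose rate decays through time as
  σ²(t) = σ₀²·e^(−r·t) with r ≥ 0.

Likelihoods are evaluated by rescaling the tree to the model's unit tree
and applying the contrasts-based BM factorization (exactly the brute-force
multivariate-normal density with covariance = model VCV + diag(se²)); the
root state z0 is profiled out at its GLS estimate during fitting.  Model
comparison uses AIC = 2k − 2·lnL with k = 2 (BM) or 3 (OU, EB) and Akaike
weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .contrasts import PruningEngine
from .expression import TraitVector
from .tree import Phylogeny, is_ultrametric, phylo_vcv  # noqa: F401 (re-export)
from .unit_tree import UnitTree, rescale_to_unit_tree, transform_lengths

MODELS = ("BM", "OU", "EB")
#: tie-break order for equal AIC and equal parameter count
MODEL_ORDER = {"BM": 0, "EB": 1, "OU": 2}

SIGSQ_BOUNDS = (1e-8, 1e4)


def alpha_bounds(T: float) -> tuple[float, float]:
    """OU selection-strength search bounds, scaled to tree height."""
    return (1e-8 / T, 50.0 / T)


def r_bounds(T: float) -> tuple[float, float]:
    """EB decay-rate search bounds; e^{rT} capped at 1e5."""
    return (0.0, math.log(1e5) / T)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one trait model.

    ``sigsq`` is σ² for BM/OU and the initial rate σ₀² for EB; ``alpha``
    and ``r`` are only meaningful for OU and EB respectively.  ``theta``
    defaults to the root state ``z0`` (single-optimum OU).
    """

    model: str
    sigsq: float
    z0: float = 0.0
    alpha: float = 0.0
    theta: float | None = None
    r: float = 0.0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not (self.sigsq > 0):
            raise ValueError("sigsq must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if self.theta is None:
            object.__setattr__(self, "theta", self.z0)

    def free_parameter_count(self) -> int:
        return {"BM": 2, "OU": 3, "EB": 3}[self.model]

    def as_dict(self) -> dict:
        return {"model": self.model, "sigsq": self.sigsq, "z0": self.z0,
                "alpha": self.alpha, "theta": self.theta, "r": self.r}


def _data_key(tree: Phylogeny, traits: TraitVector) -> tuple:
    labels = tuple(tree.tip_labels)
    vals = tuple(float(traits.values[t]) for t in labels)
    ses = tuple(float(traits.se[t]) for t in labels)
    return (traits.gene, traits.tissue, labels, vals, ses)


def _aligned(tree: Phylogeny, traits: TraitVector) -> TraitVector:
    tips = tree.tip_labels
    missing = [t for t in tips if t not in traits.values.index]
    if missing:
        raise KeyError(f"traits missing for tip(s): {missing}")
    return traits.reorder(tips)


def model_loglik(tree: Phylogeny, traits: TraitVector, params: ModelParams) -> float:
    """Gaussian log-likelihood of tip data under a model with root state z0.

    Computed via the model's branch-length transform followed by the
    contrasts-based BM(σ=1) likelihood; equal to the brute-force
    multivariate-normal log-density with covariance = model VCV + diag(se²).
    OU/EB require an ultrametric tree.
    """
    traits = _aligned(tree, traits)
    lengths = transform_lengths(tree, params, traits.se)
    d = tree.depths(lengths)
    if d[tree.tip_indices].max() <= 0:
        raise ValueError("singular covariance: zero branch lengths and zero SE")
    engine = PruningEngine(tree, lengths)
    values = traits.values.to_numpy()
    ll, _ = engine.loglik(values, z0=params.z0)
    return float(ll)


@dataclass
class ModelFit:
    """A fitted trait model: the results object returned by ``fit``.

    Carries the ML parameters, log-likelihood, AIC, and fitting
    diagnostics; the unit tree and the adequacy test hang off it.
    """

    params: ModelParams
    lnL: float
    k: int
    aic: float
    n_tips: int
    converged: bool
    restarts_used: int
    notes: tuple = ()
    _tree: Phylogeny | None = field(default=None, repr=False)
    _traits: TraitVector | None = field(default=None, repr=False)
    data_key: tuple = field(default=(), repr=False)

    @property
    def model(self) -> str:
        return self.params.model

    def unit_tree(self) -> UnitTree:
        """Rescale the fitting tree under the fitted parameters (+ tip se²)."""
        se = {t: float(self._traits.se[t]) for t in self._tree.tip_labels}
        return rescale_to_unit_tree(self._tree, self.params, se)

    def adequacy(self, n_sim: int = 1000, seed: int = 0):
        """Parametric-bootstrap adequacy test of this fit; see `adexpr.adequacy`."""
        from . import adequacy as adq
        from .contrasts import compute_pics

        utree = self.unit_tree()
        cs = compute_pics(utree, self._traits)
        observed = adq.observed_stats(cs)
        null = adq.simulate_null(utree, n_sim=n_sim, seed=seed)
        return adq.adequacy_pvalues(observed, null, n_sim=n_sim, seed=seed)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"{self.model} trait model fit (n_tips={self.n_tips})",
            "-" * 44,
            f"log-likelihood  {self.lnL:12.4f}",
            f"AIC             {self.aic:12.4f}   (k={self.k})",
            f"sigsq           {p.sigsq:12.6g}",
            f"z0              {p.z0:12.6g}",
        ]
        if self.model == "OU":
            lines.append(f"alpha           {p.alpha:12.6g}")
            lines.append(f"theta           {p.theta:12.6g}   (= z0)")
        if self.model == "EB":
            lines.append(f"r               {p.r:12.6g}")
        lines.append(f"converged       {self.converged}   "
                     f"(restarts={self.restarts_used})")
        if self.notes:
            lines.append("notes: " + "; ".join(self.notes))
        return "\n".join(lines)


class PhyloTraitModel:
    """A trait model bound to data, in the Model → fit() → Results idiom.

    Parameters
    ----------
    tree : Phylogeny
        Bifurcating tree whose tips all have trait data (prune first).
    traits : TraitVector
        Species means and standard errors (log scale).
    model : str
        "BM", "OU", or "EB".
    """

    def __init__(self, tree: Phylogeny, traits: TraitVector, model: str = "BM"):
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        self.model = model
        self.tree = tree
        self.traits = _aligned(tree, traits)
        if tree.n_tips < 2:
            raise ValueError("need at least 2 tips")
        if model in ("OU", "EB") and not is_ultrametric(tree):
            raise ValueError(f"{model} requires an ultrametric tree")
        self._values = self.traits.values.to_numpy()
        self._se = self.traits.se
        self._T = tree.height

    @classmethod
    def from_expression(cls, tree: Phylogeny, matrix, gene: str,
                        tissue: str | None = None, model: str = "BM"):
        """Build from a log ExpressionMatrix by collapsing replicates."""
        from .expression import summarize_replicates
        from .tree import prune_tips

        tv = summarize_replicates(matrix, gene, tissue)
        shared = [t for t in tree.tip_labels if t in tv.values.index]
        sub = prune_tips(tree, shared) if len(shared) < tree.n_tips else tree
        return cls(sub, tv, model=model)

    def loglik(self, params: ModelParams) -> float:
        return model_loglik(self.tree, self.traits, params)

    # -- internals -----------------------------------------------------

    def _profiled_nll(self, model: str, sigsq: float, alpha: float, r: float):
        """−lnL with the root state profiled at its GLS estimate."""
        params = ModelParams(model=model, sigsq=sigsq, alpha=alpha, r=r)
        lengths = transform_lengths(self.tree, params, self._se)
        engine = PruningEngine(self.tree, lengths)
        ll, zhat = engine.loglik(self._values, z0=None)
        return -ll, zhat

    def _bm_closed_form(self) -> float | None:
        """ML σ̂² = Σ pic² / n when all SEs are zero (else None)."""
        if (self._se.to_numpy() != 0).any():
            return None
        engine = PruningEngine(self.tree)
        pics, _, _ = engine.contrasts(self._values)
        s = float((pics ** 2).sum())
        return s / self.tree.n_tips

    def fit(self, restarts: int = 3, seed: int = 0) -> ModelFit:
        """Maximum-likelihood fit by bounded numerical optimization.

        σ² (and α for OU) are searched on the log scale; the EB decay r on
        the natural scale; the root state is profiled analytically.
        Deterministic given ``seed`` (which only drives the jitter of the
        stratified multistart for OU/EB).
        """
        lo_s, hi_s = math.log(SIGSQ_BOUNDS[0]), math.log(SIGSQ_BOUNDS[1])
        notes: list[str] = []
        if self.model == "BM":
            def nll(ls):
                return self._profiled_nll("BM", math.exp(ls), 0.0, 0.0)[0]

            res = optimize.minimize_scalar(
                nll, bounds=(lo_s, hi_s), method="bounded",
                options={"xatol": 1e-10})
            best_ls, best_nll = float(res.x), float(res.fun)
            cf = self._bm_closed_form()
            if cf is not None and SIGSQ_BOUNDS[0] <= cf <= SIGSQ_BOUNDS[1]:
                v = nll(math.log(cf))
                if v < best_nll:
                    best_ls, best_nll = math.log(cf), v
            sigsq, alpha, r = math.exp(best_ls), 0.0, 0.0
            success, restarts_used = bool(res.success), 1
        else:
            rng = np.random.default_rng(seed)
            bm_sig = self._bm_closed_form()
            if bm_sig is None or not np.isfinite(bm_sig) or bm_sig <= 0:
                f = optimize.minimize_scalar(
                    lambda ls: self._profiled_nll("BM", math.exp(ls), 0, 0)[0],
                    bounds=(lo_s, hi_s), method="bounded")
                bm_sig = math.exp(float(f.x))
            T = self._T
            if self.model == "OU":
                a_lo, a_hi = alpha_bounds(T)
                la_lo, la_hi = math.log(a_lo), math.log(a_hi)
                bounds = [(lo_s, hi_s), (la_lo, la_hi)]

                def nll_vec(x):
                    try:
                        return self._profiled_nll(
                            "OU", math.exp(x[0]), math.exp(x[1]), 0.0)[0]
                    except (ValueError, FloatingPointError):
                        return 1e10

                def start(i):
                    u = rng.uniform()
                    la = la_lo + (i + u) / restarts * (la_hi - la_lo)
                    a = math.exp(la)
                    # match the BM tip variance at this alpha
                    s0 = bm_sig * T * 2 * a / (-np.expm1(-2 * a * T))
                    return [np.clip(math.log(s0), lo_s, hi_s), la]
            else:  # EB
                r_lo, r_hi = r_bounds(T)
                bounds = [(lo_s, hi_s), (r_lo, r_hi)]

                def nll_vec(x):
                    try:
                        return self._profiled_nll(
                            "EB", math.exp(x[0]), 0.0, x[1])[0]
                    except (ValueError, FloatingPointError):
                        return 1e10

                def start(i):
                    u = rng.uniform()
                    rv = (i + u) / restarts * 0.8 * r_hi
                    s0 = bm_sig if rv == 0 else bm_sig * T * rv / (-np.expm1(-rv * T))
                    return [np.clip(math.log(s0), lo_s, hi_s), rv]

            best, success = None, False
            for i in range(restarts):
                res = optimize.minimize(
                    nll_vec, start(i), method="L-BFGS-B", bounds=bounds)
                if best is None or res.fun < best.fun:
                    best, success = res, bool(res.success)
            if best is None or not np.isfinite(best.fun):
                raise RuntimeError(
                    f"{self.model} optimization failed on all {restarts} restarts")
            restarts_used = restarts
            sigsq = math.exp(best.x[0])
            alpha = math.exp(best.x[1]) if self.model == "OU" else 0.0
            r = best.x[1] if self.model == "EB" else 0.0
            best_nll = float(best.fun)
            if self.model == "OU" and not (a_lo * 1.0001 < alpha < a_hi / 1.0001):
                notes.append("alpha at search bound")
            if self.model == "EB" and r > r_bounds(T)[1] * 0.9999:
                notes.append("r at search bound")

        at_sig_bound = not (SIGSQ_BOUNDS[0] * 1.0001 < sigsq
                            < SIGSQ_BOUNDS[1] / 1.0001)
        if at_sig_bound:
            notes.append("sigsq at search bound")
        nll, zhat = self._profiled_nll(self.model, sigsq, alpha, r)
        params = ModelParams(model=self.model, sigsq=sigsq, z0=zhat,
                             alpha=alpha, r=r)
        k = params.free_parameter_count()
        lnL = -float(nll)
        return ModelFit(
            params=params, lnL=lnL, k=k, aic=2 * k - 2 * lnL,
            n_tips=self.tree.n_tips, converged=success and not at_sig_bound,
            restarts_used=restarts_used, notes=tuple(notes),
            _tree=self.tree, _traits=self.traits,
            data_key=_data_key(self.tree, self.traits))


def fit_model(tree: Phylogeny, traits: TraitVector, model: str,
              restarts: int = 3, seed: int = 0) -> ModelFit:
    """Functional wrapper: ``PhyloTraitModel(tree, traits, model).fit()``."""
    return PhyloTraitModel(tree, traits, model=model).fit(
        restarts=restarts, seed=seed)


@dataclass
class ModelComparison:
    """AIC comparison across candidate fits of the same data."""

    fits: dict[str, ModelFit]
    delta_aic: dict[str, float]
    weights: dict[str, float]
    best: str

    @property
    def best_fit(self) -> ModelFit:
        return self.fits[self.best]

    def summary(self) -> str:
        lines = [f"{'model':6} {'lnL':>10} {'AIC':>10} {'dAIC':>8} {'weight':>8}"]
        for m in sorted(self.fits, key=lambda m: self.delta_aic[m]):
            f = self.fits[m]
            lines.append(f"{m:6} {f.lnL:10.3f} {f.aic:10.3f} "
                         f"{self.delta_aic[m]:8.3f} {self.weights[m]:8.4f}")
        lines.append(f"best model: {self.best}")
        return "\n".join(lines)


def compare_models(fits) -> ModelComparison:
    """Rank fits by AIC; Akaike weights; deterministic tie-breaking.

    Ties on AIC go to the model with fewer parameters, then to the fixed
    order BM < EB < OU.  All fits must be of the same data.
    """
    fits = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if len(fits) < 2:
        raise ValueError("compare_models needs at least 2 fits")
    keys = {f.data_key for f in fits}
    if len(keys) != 1:
        raise ValueError("fits are not all of the same data")
    names = [f.model for f in fits]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model fits supplied")
    by_name = {f.model: f for f in fits}
    aic = {m: by_name[m].aic for m in by_name}
    best = min(by_name, key=lambda m: (aic[m], by_name[m].k, MODEL_ORDER[m]))
    delta = {m: aic[m] - aic[best] for m in by_name}
    raw = {m: math.exp(-delta[m] / 2) for m in by_name}
    tot = sum(raw.values())
    weights = {m: raw[m] / tot for m in by_name}
    return ModelComparison(fits=by_name, delta_aic=delta, weights=weights,
                           best=best)


def fit_all(tree: Phylogeny, traits: TraitVector,
            models=MODELS, restarts: int = 3, seed: int = 0) -> ModelComparison:
    """Fit several models to one dataset and compare them by AIC."""
    fits = [fit_model(tree, traits, m, restarts=restarts, seed=seed)
            for m in models]
    return compare_models(fits)
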