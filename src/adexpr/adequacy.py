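"""Model adequacy: five contrast summary statistics and a bootstrap null.

If a fitted model describes the data well, the independent contrasts on
its unit tree are i.i.d. N(0, 1).  Five summary statistics probe distinct
departures from that expectation:

* ``c.var``  — coefficient of variation of |PIC|: unmodeled rate
  heterogeneity across the tree.
* ``d.cdf``  — Kolmogorov–Smirnov D between the contrasts and N(0, 1):
  non-normality, e.g. bursts of change.
* ``s.asr``  — OLS slope of |PIC| on the node's ancestral-state estimate:
  rate depending on trait value.
* ``s.hgt``  — OLS slope of |PIC| on node height (the "node height test"):
  rate changing through time, e.g. early bursts.
* ``s.var``  — OLS slope of |PIC| on the contrast's expected variance:
  branch-length misspecification.

The null distribution of each statistic is obtained by parametric
bootstrap: simulate BM(σ=1) datasets on the unit tree (tip measurement
variance is already baked into the terminal branches) and push each
through the identical statistic kernels.  A statistic whose observed value
falls in either tail of its null yields a small two-tailed Monte-Carlo
p-value; p < 0.05 flags the model as performing poorly for that gene.

A slope statistic is NA when its predictor is (numerically) constant —
notably s.hgt under a large fitted OU α, where almost all unit-tree length
is in the terminal branches and node heights carry essentially no
variance.  NA statistics propagate to NA p-values and are excluded from
the "adequate" verdict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .contrasts import ContrastSet, PruningEngine
from .unit_tree import UnitTree

STAT_NAMES = ("c.var", "d.cdf", "s.asr", "s.hgt", "s.var")

#: relative variance below which a slope predictor counts as constant
_SLOPE_VAR_TOL = 1e-12


# -- batch kernels (columns = datasets; observed data is a 1-column batch) --

def _cvar_batch(abs_pics: np.ndarray) -> np.ndarray:
    k = abs_pics.shape[0]
    if k < 2:
        return np.full(abs_pics.shape[1], np.nan)
    mean = abs_pics.mean(axis=0)
    sd = abs_pics.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean > 0, sd / mean, np.nan)
    return out


def _dcdf_batch(pics: np.ndarray) -> np.ndarray:
    k = pics.shape[0]
    xs = np.sort(pics, axis=0)
    cdf = norm.cdf(xs)
    i = np.arange(1, k + 1)[:, None] / k
    return np.maximum(i - cdf, cdf - (i - 1 / k)).max(axis=0)


def _slope_batch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS slope of y on x per column; NA for a degenerate predictor."""
    k = x.shape[0]
    if x.shape != y.shape:
        raise ValueError("slope inputs must have equal shapes")
    if k < 2:
        return np.full(x.shape[1], np.nan)
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    varx = sxx / (k - 1)
    degenerate = varx < _SLOPE_VAR_TOL * np.maximum(1.0, xm ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(degenerate, np.nan, sxy / sxx)
    return out


def _batch_stats(pics: np.ndarray, xhat: np.ndarray, heights: np.ndarray,
                 v_exp: np.ndarray) -> dict[str, np.ndarray]:
    """All five statistics for a (n_contrasts, m) batch of contrast sets."""
    m = pics.shape[1]
    abs_pics = np.abs(pics)
    hts = np.broadcast_to(heights[:, None], (len(heights), m))
    vex = np.broadcast_to(v_exp[:, None], (len(v_exp), m))
    return {
        "c.var": _cvar_batch(abs_pics),
        "d.cdf": _dcdf_batch(pics),
        "s.asr": _slope_batch(xhat, abs_pics),
        "s.hgt": _slope_batch(hts, abs_pics),
        "s.var": _slope_batch(vex, abs_pics),
    }


# -- single-sample operations -------------------------------------------

def stat_cvar(cs: ContrastSet) -> float:
    """sd(|pic|)/mean(|pic|) with an n−1 denominator; NA if all pics are 0."""
    return float(_cvar_batch(np.abs(cs.pic)[:, None])[0])


def stat_dcdf(cs: ContrastSet) -> float:
    """Two-sided KS D between the signed contrasts and the standard normal."""
    return float(_dcdf_batch(cs.pic[:, None])[0])


def stat_slope(x, y) -> float:
    """OLS slope of y on x; NA when the predictor is numerically constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("stat_slope inputs must have equal lengths")
    return float(_slope_batch(x[:, None], y[:, None])[0])


def observed_stats(cs: ContrastSet) -> dict[str, float]:
    """The five statistics of one observed contrast set (NaN encodes NA)."""
    out = _batch_stats(cs.pic[:, None], cs.xhat[:, None], cs.height, cs.v_exp)
    return {k: float(v[0]) for k, v in out.items()}


def simulate_null(utree: UnitTree, n_sim: int = 1000,
                  seed: int = 0) -> dict[str, np.ndarray]:
    """Parametric-bootstrap null draws of the five statistics.

    Simulates ``n_sim`` datasets as BM(σ=1) from root state 0 on the unit
    tree and reduces each through the same statistic kernels used for the
    observed data.  Deterministic given ``seed``.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a usable null")
    engine = PruningEngine(utree.tree)
    rng = np.random.default_rng(seed)
    tips = engine.simulate_bm(n_sim, rng)
    pics, xhat, _ = engine.contrasts(tips)
    return _batch_stats(pics, xhat, engine.node_heights, engine.v_exp)


@dataclass
class AdequacyResult:
    """Observed statistics, their bootstrap nulls, and two-tailed p-values.

    p-values are add-one Monte-Carlo estimates in (0, 1]; NaN marks an NA
    statistic.  ``adequate()`` is True when every non-NA p-value is at or
    above the cutoff, and None when all five are NA.
    """

    observed: dict[str, float]
    null: dict[str, np.ndarray]
    pvalues: dict[str, float]
    n_sim: int
    seed: int

    def adequate(self, alpha: float = 0.05) -> bool | None:
        ps = [p for p in self.pvalues.values() if not np.isnan(p)]
        if not ps:
            return None
        return all(p >= alpha for p in ps)

    def summary(self) -> str:
        lines = [f"{'statistic':10} {'observed':>10} {'p':>8}"]
        for s in STAT_NAMES:
            o, p = self.observed[s], self.pvalues[s]
            ostr = f"{o:10.4f}" if not np.isnan(o) else f"{'NA':>10}"
            pstr = f"{p:8.4f}" if not np.isnan(p) else f"{'NA':>8}"
            lines.append(f"{s:10} {ostr} {pstr}")
        verdict = self.adequate()
        lines.append(f"adequate at 0.05: {verdict}   (n_sim={self.n_sim})")
        return "\n".join(lines)


def adequacy_pvalues(observed: dict[str, float], null: dict[str, np.ndarray],
                     n_sim: int | None = None, seed: int = 0) -> AdequacyResult:
    """Two-tailed Monte-Carlo p-values from a shared batch of null draws.

    p = 2·min(1 + #(null ≤ obs), 1 + #(null ≥ obs)) / (n_valid + 1),
    capped at 1, computed over the non-NA null draws; an NA observed
    statistic yields an NA p-value.
    """
    pvals: dict[str, float] = {}
    for s in STAT_NAMES:
        obs = observed[s]
        if np.isnan(obs):
            pvals[s] = np.nan
            continue
        draws = np.asarray(null[s], float)
        valid = draws[~np.isnan(draws)]
        if valid.size == 0:
            warnings.warn(f"all null draws NA for {s}; p-value is NA")
            pvals[s] = np.nan
            continue
        n_le = int((valid <= obs).sum())
        n_ge = int((valid >= obs).sum())
        p = 2.0 * min(n_le + 1, n_ge + 1) / (valid.size + 1)
        pvals[s] = min(1.0, p)
    if n_sim is None:
        n_sim = max(len(np.asarray(v)) for v in null.values())
    return AdequacyResult(observed=dict(observed), null=dict(null),
                         pvalues=pvals, n_sim=n_sim, seed=seed)
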