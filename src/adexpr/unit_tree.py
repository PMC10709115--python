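"""Branch-length rescaling to the "unit tree" of a fitted model.

Each branch's new length is the trait variance the fitted model accrues
along it, so that — if the model is the generating one — the data on the
rescaled tree are distributed as Brownian motion with σ = 1, and the
independent contrasts are i.i.d. N(0, 1).  Per-tip squared standard errors
are added to the terminal branches afterwards, because measurement variance
lives on the data scale, not the evolutionary-time scale.

For a branch spanning depths [t₁, t₂] from the root on a tree of height T:

    BM:  σ²·(t₂ − t₁)
    OU:  (σ²/2α)·(e^{−2α(T−t₂)} − e^{−2α(T−t₁)})      (ultrametric only)
    EB:  σ₀²·(e^{−r·t₁} − e^{−r·t₂})/r                 (ultrametric only)

with the α→0 / r→0 limits reducing to BM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .tree import Phylogeny, is_ultrametric

if TYPE_CHECKING:  # pragma: no cover
    from .models import ModelParams


def transform_lengths(tree: Phylogeny, params: "ModelParams",
                      se: Mapping[str, float] | None = None) -> np.ndarray:
    """Model-variance branch lengths for ``tree`` under ``params``.

    Returns a branch-length vector indexed like ``tree.length`` (the root
    entry transforms any root edge, which spans depths [0, stem]).  OU and
    EB require an ultrametric tree.  ``se`` maps tip label → standard
    error; se² is added to the terminal branches.
    """
    d = tree.depths()
    t2 = d
    t1 = np.where(tree.parent >= 0, d[tree.parent], 0.0)
    dt = t2 - t1

    model = params.model
    if model == "BM":
        out = params.sigsq * dt
    elif model in ("OU", "EB"):
        if not is_ultrametric(tree):
            raise ValueError(f"{model} rescaling requires an ultrametric tree")
        if model == "OU":
            a = params.alpha
            if a == 0.0:
                out = params.sigsq * dt
            else:
                T = tree.height
                # (σ²/2α)(e^{-2α(T-t2)} - e^{-2α(T-t1)}), expm1 for small α
                out = (params.sigsq / (2 * a)) * np.exp(-2 * a * (T - t2)) \
                    * (-np.expm1(-2 * a * dt))
        else:  # EB
            r = params.r
            if r == 0.0:
                out = params.sigsq * dt
            else:
                # σ₀²(e^{-r t1} - e^{-r t2})/r
                out = (params.sigsq / r) * np.exp(-r * t1) * (-np.expm1(-r * dt))
    else:  # pragma: no cover - ModelParams validates
        raise ValueError(f"unknown model {model!r}")

    out = np.asarray(out, dtype=float)
    if tree.root_edge == 0.0:
        out[tree.root] = 0.0
    if se is not None:
        for i in tree.tip_indices:
            s = se.get(tree.labels[i], 0.0) if hasattr(se, "get") else se[tree.labels[i]]
            out[i] += float(s) ** 2
    return out


@dataclass
class UnitTree:
    """A phylogeny whose branch lengths are accumulated model variance.

    ``tree`` carries the rescaled lengths; ``params`` records the source
    model and ``se`` the per-tip standard errors whose squares were added
    to the terminal branches.  The root-to-tip length of tip i equals the
    model's marginal trait variance at that tip plus se_i².
    """

    tree: Phylogeny
    params: "ModelParams"
    se: dict = field(default_factory=dict)

    @property
    def tip_labels(self):
        return self.tree.tip_labels

    def tip_variances(self) -> dict[str, float]:
        d = self.tree.depths()
        return {self.tree.labels[i]: float(d[i]) for i in self.tree.tip_indices}

    def to_newick(self) -> str:
        return self.tree.to_newick()


def rescale_to_unit_tree(tree: Phylogeny, params: "ModelParams",
                         se: Mapping[str, float] | None = None) -> UnitTree:
    """Rescale ``tree`` under a fitted model; see :func:`transform_lengths`."""
    lengths = transform_lengths(tree, params, se)
    se_dict = {} if se is None else {k: float(se[k]) for k in
                                     (se.keys() if hasattr(se, "keys") else [])}
    return UnitTree(tree=tree.with_lengths(lengths), params=params, se=se_dict)
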