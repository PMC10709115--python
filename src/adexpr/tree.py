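"""Rooted phylogenies with branch lengths: parsing, validation, manipulation.

Trees are stored in a flat array form (parent pointers, branch lengths,
child lists, postorder) that the likelihood and contrast machinery can
traverse cheaply.  Newick reading/writing is delegated to dendropy; all
structural operations (pruning, polytomy resolution, depth bookkeeping) are
implemented here.

A tree may carry a *root edge* (``length[root] > 0``): a stem above the
root node.  It arises when pruning reduces a tree to a clade — retaining
the stem keeps every kept tip's root-to-tip distance unchanged.  The stem
contributes shared evolutionary history: it is added to every entry of the
phylogenetic covariance matrix and to the variance of the root-state
estimate in the pruning likelihood, but it never enters a contrast.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import numpy as np

try:  # dendropy is a hard dependency; import error surfaces at use time
    import dendropy
except ImportError as _e:  # pragma: no cover
    dendropy = None
    _dendropy_err = _e


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally invalid phylogeny (duplicate labels, bad lengths, ...)."""


class Phylogeny:
    """A rooted phylogeny with branch lengths in time units.

    Parameters
    ----------
    parent : array of int
        Parent index per node; -1 for the root (exactly one).
    length : array of float
        Branch length above each node; entry at the root is the root-edge
        (stem) length, 0.0 when absent. All lengths must be >= 0.
    labels : sequence of str or None
        Tip labels; internal nodes carry ``None``.
    """

    def __init__(self, parent: Sequence[int], length: Sequence[float],
                 labels: Sequence[str | None], validate: bool = True):
        self.parent = np.asarray(parent, dtype=np.intp)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        self._postorder: np.ndarray | None = None
        self._preorder: np.ndarray | None = None
        self._depths: np.ndarray | None = None
        if validate:
            self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        if np.any(self.length < 0) or not np.all(np.isfinite(self.length)):
            raise TreeValidationError("all branch lengths must be finite and >= 0")
        tips = [self.labels[i] for i in np.flatnonzero(self.is_tip)]
        if len(tips) < 2:
            raise TreeValidationError("a phylogeny needs at least 2 tips")
        if any(t is None for t in tips):
            raise TreeValidationError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        # connectivity / acyclicity: postorder must reach every node
        if self.postorder.size != self.parent.size:
            raise TreeValidationError("tree is not connected")

    # -- basic properties ----------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def root_edge(self) -> float:
        return float(self.length[self.root])

    @property
    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        if self._postorder is None:
            order, stack = [], [(self.root, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    order.append(node)
                else:
                    stack.append((node, True))
                    for c in self.children[node]:
                        stack.append((c, False))
            self._postorder = np.array(order, dtype=np.intp)
        return self._postorder

    @property
    def preorder(self) -> np.ndarray:
        if self._preorder is None:
            self._preorder = self.postorder[::-1].copy()
        return self._preorder

    def depths(self, lengths: np.ndarray | None = None) -> np.ndarray:
        """Distance from the top of the root edge to each node.

        The root node sits at depth ``root_edge`` (0 when no stem).
        Optionally computed under an alternative branch-length vector.
        """
        if lengths is None:
            if self._depths is not None:
                return self._depths
            lengths = self.length
            cache = True
        else:
            lengths = np.asarray(lengths, dtype=float)
            cache = False
        d = np.empty(self.n_nodes)
        for node in self.preorder:
            p = self.parent[node]
            d[node] = lengths[node] + (d[p] if p >= 0 else 0.0)
        if cache:
            self._depths = d
        return d

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth (including any root edge)."""
        return float(self.depths()[self.tip_indices].max())

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def with_lengths(self, lengths: Iterable[float]) -> "Phylogeny":
        """Copy of this tree with a different branch-length vector."""
        return Phylogeny(self.parent, lengths, self.labels, validate=False)

    # -- Newick ---------------------------------------------------------

    def to_newick(self) -> str:
        out = io.StringIO()

        def walk(node: int) -> None:
            kids = self.children[node]
            if kids:
                out.write("(")
                for j, c in enumerate(kids):
                    if j:
                        out.write(",")
                    walk(c)
                out.write(")")
            else:
                out.write(self.labels[node])
            if self.parent[node] >= 0:
                out.write(f":{float(self.length[node])!r}")

        walk(self.root)
        if self.root_edge > 0:
            out.write(f":{float(self.root_edge)!r}")
        out.write(";")
        return out.getvalue()

    def __repr__(self) -> str:
        return f"<Phylogeny: {self.n_tips} tips, height {self.height:.4g}>"

    # -- queries ----------------------------------------------------------

    def patristic_distance(self, a: str, b: str) -> float:
        idx = {self.labels[i]: i for i in self.tip_indices}
        d = self.depths()
        i, j = idx[a], idx[b]
        anc_i = set()
        k = i
        while k >= 0:
            anc_i.add(k)
            k = self.parent[k]
        k = j
        while k not in anc_i:
            k = self.parent[k]
        return float(d[i] + d[j] - 2 * d[k])


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick string into a :class:`Phylogeny`.

    Branch lengths are required on all non-root edges; internal node labels
    are ignored. Raises :class:`NewickParseError` for malformed input and
    :class:`TreeValidationError` for duplicate tip labels or bad lengths.
    """
    if dendropy is None:  # pragma: no cover
        raise _dendropy_err
    text = text.strip()
    if not text:
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            terminating_semicolon_required=True,
        )
    except Exception as e:  # dendropy raises several error types
        if "Duplicate taxon labels" in str(e):
            raise TreeValidationError(f"duplicate tip labels: {e}") from None
        raise NewickParseError(f"malformed Newick: {e}") from None
    return _from_dendropy(dtree)


def _from_dendropy(dtree: "dendropy.Tree") -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent, length, labels = [], [], []
    for i, nd in enumerate(nodes):
        if nd.parent_node is None:
            parent.append(-1)
            length.append(nd.edge.length or 0.0)
        else:
            parent.append(index[id(nd.parent_node)])
            if nd.edge.length is None:
                raise TreeValidationError(
                    "branch length missing on a non-root edge")
            length.append(nd.edge.length)
        labels.append(nd.taxon.label if nd.taxon is not None else None)
    return Phylogeny(parent, length, labels)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_newick_trees(path) -> list[Phylogeny]:
    """Read every tree in a multi-tree Newick file, in order."""
    with open(path) as fh:
        content = fh.read()
    chunks = [c.strip() for c in content.split(";") if c.strip()]
    return [parse_newick(c + ";") for c in chunks]


def write_newick(tree: Phylogeny, path=None) -> str:
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def prune_tips(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Induced subtree on the tip set ``keep``.

    Unbranched internal nodes are suppressed with their lengths summed; if
    the kept tips' MRCA is below the root, the path above it is retained as
    a root edge, so every kept tip's root-to-tip distance is unchanged and
    patristic distances among kept tips are preserved exactly.
    """
    keep = set(keep)
    tip_set = set(tree.tip_labels)
    unknown = sorted(keep - tip_set)
    if unknown:
        raise KeyError(f"labels not in tree: {unknown}")
    if len(keep) < 2:
        raise ValueError("prune_tips needs at least 2 tips to keep")

    n = tree.n_nodes
    retained = np.zeros(n, dtype=bool)
    for node in tree.postorder:
        if tree.is_tip[node]:
            retained[node] = tree.labels[node] in keep
        else:
            retained[node] = any(retained[c] for c in tree.children[node])

    parent_out: list[int] = []
    length_out: list[float] = []
    labels_out: list[str | None] = []

    def build(node: int, extra: float, new_parent: int) -> None:
        kids = [c for c in tree.children[node] if retained[c]]
        blen = tree.length[node] + extra
        if not kids:  # kept tip
            parent_out.append(new_parent)
            length_out.append(blen)
            labels_out.append(tree.labels[node])
            return
        if len(kids) == 1:  # suppress unary pass-through, summing lengths
            build(kids[0], blen, new_parent)
            return
        me = len(parent_out)
        parent_out.append(new_parent)
        length_out.append(blen)
        labels_out.append(None)
        for c in kids:
            build(c, 0.0, me)

    # descend from the original root to the first node with >=2 kept
    # children (the kept MRCA), accumulating stem length
    node, extra = tree.root, 0.0
    while True:
        kids = [c for c in tree.children[node] if retained[c]]
        if len(kids) >= 2 or tree.is_tip[node]:
            break
        extra += tree.length[node] if node != tree.root else tree.root_edge
        node = kids[0]
    stem = extra + (tree.length[node] if node != tree.root else tree.root_edge)
    me = len(parent_out)
    parent_out.append(-1)
    length_out.append(stem)
    labels_out.append(None)
    for c in [c for c in tree.children[node] if retained[c]]:
        build(c, 0.0, me)
    return Phylogeny(parent_out, length_out, labels_out)


def is_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip depths agree to ``rel_tol`` × tree height."""
    d = tree.depths()[tree.tip_indices]
    height = d.max()
    return bool(d.max() - d.min() <= rel_tol * height)


def resolve_polytomies(tree: Phylogeny, seed: int = 0) -> Phylogeny:
    """Resolve every polytomy into zero-length bifurcations.

    Children at each multifurcating node are combined pairwise in a
    rng-shuffled order (deterministic given ``seed``); the inserted edges
    have length 0, so tip depths and the phylogenetic covariance matrix are
    unchanged.  An already-binary tree is returned as-is.
    """
    if tree.is_binary():
        return tree
    rng = np.random.default_rng(seed)
    parent = list(tree.parent)
    length = list(tree.length)
    labels = list(tree.labels)
    for node in range(tree.n_nodes):
        kids = [i for i, p in enumerate(parent) if p == node]
        if len(kids) <= 2:
            continue
        kids = [kids[i] for i in rng.permutation(len(kids))]
        while len(kids) > 2:
            a = kids.pop()
            b = kids.pop()
            new = len(parent)
            parent.append(node)
            length.append(0.0)
            labels.append(None)
            parent[a] = new
            parent[b] = new
            kids.append(new)
    return Phylogeny(parent, length, labels)


def phylo_vcv(tree: Phylogeny):
    """Phylogenetic variance–covariance matrix C (species × species).

    C[i, j] is the depth of the MRCA of tips i and j — the shared
    evolutionary history; C[i, i] is tip i's root-to-tip depth.  Any root
    edge is shared by all tips and adds to every entry.  Quadratic in the
    number of tips; used as the brute-force oracle for the pruning-based
    likelihood, not on large trees.

    Returns ``(labels, C)`` with labels in tip order.
    """
    d = tree.depths()
    tips = tree.tip_indices
    labels = [tree.labels[i] for i in tips]
    # ancestor paths per tip
    paths = []
    for t in tips:
        anc = {}
        k = t
        while k >= 0:
            anc[k] = d[k]
            k = tree.parent[k]
        paths.append(anc)
    n = len(tips)
    C = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                C[i, i] = d[tips[i]]
            else:
                shared = max(v for k, v in paths[i].items() if k in paths[j])
                C[i, j] = C[j, i] = shared
    return labels, C
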