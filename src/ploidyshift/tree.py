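"""Array-backed rooted time trees.

A :class:`TimeTree` stores a rooted phylogeny with branch lengths in time
units as parallel arrays indexed by an integer node id.  Tips occupy ids
``0 .. n_tips-1``; internal nodes follow, with the root always the last node
of the postorder.  This layout makes the pruning-algorithm likelihoods,
Brownian-motion reconstructions and character-history simulators in the rest
of the package simple loops over flat arrays.

Trees are converted to and from :mod:`dendropy` for Newick/Nexus handling;
dendropy is the single parser/writer used by :mod:`ploidyshift.tree_io`.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["TimeTree", "MissingBranchLengthError", "TreeStructureError"]


class TreeStructureError(ValueError):
    """The node/branch arrays do not describe a valid rooted tree."""


class MissingBranchLengthError(ValueError):
    """A non-root edge has no branch length.

    Every model in this package is time-calibrated, so a defaulted branch
    length would silently change the meaning of every rate estimate; missing
    lengths are therefore fatal.
    """


class TimeTree:
    """Rooted tree with branch lengths, tips first in the node numbering.

    Parameters
    ----------
    parent
        ``parent[v]`` is the parent id of node ``v``; ``-1`` for the root.
    blen
        ``blen[v]`` is the length of the branch *above* node ``v`` (time
        units, >= 0).  The root entry is ignored and stored as 0.
    tip_labels
        Labels for nodes ``0 .. n_tips-1``; must be unique.
    """

    __slots__ = (
        "parent",
        "blen",
        "tip_labels",
        "n_tips",
        "n_nodes",
        "root",
        "children",
        "_postorder",
        "_depths",
        "_nlevels",
    )

    def __init__(self, parent: Sequence[int], blen: Sequence[float], tip_labels: Sequence[str]):
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.blen = np.asarray(blen, dtype=float).copy()
        self.tip_labels = [str(x) for x in tip_labels]
        self.n_nodes = int(self.parent.shape[0])
        self.n_tips = len(self.tip_labels)
        if self.blen.shape[0] != self.n_nodes:
            raise TreeStructureError("parent and blen arrays differ in length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeStructureError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.blen[self.root] = 0.0
        if not np.all(np.isfinite(self.blen)):
            raise TreeStructureError("non-finite branch length")
        if np.any(self.blen < 0):
            raise TreeStructureError("negative branch length")
        if len(set(self.tip_labels)) != self.n_tips:
            raise TreeStructureError("tip labels are not unique")

        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = int(self.parent[v])
            if p >= 0:
                children[p].append(v)
        self.children = children
        for v in range(self.n_tips):
            if children[v]:
                raise TreeStructureError(f"tip node {v} has children")
        for v in range(self.n_tips, self.n_nodes):
            if not children[v]:
                raise TreeStructureError(f"internal node {v} has no children")
        self._postorder: np.ndarray | None = None
        self._depths: np.ndarray | None = None
        self._nlevels: np.ndarray | None = None

    # ------------------------------------------------------------------ #
    # traversal / geometry
    # ------------------------------------------------------------------ #
    @property
    def postorder(self) -> np.ndarray:
        """Node ids with every child before its parent (root last)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [(self.root, False)]
            while stack:
                v, done = stack.pop()
                if done:
                    order.append(v)
                else:
                    stack.append((v, True))
                    for c in reversed(self.children[v]):
                        stack.append((c, False))
            self._postorder = np.asarray(order, dtype=np.int64)
        return self._postorder

    @property
    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for v in self.preorder:
                p = int(self.parent[v])
                if p >= 0:
                    d[v] = d[p] + self.blen[v]
            self._depths = d
        return self._depths

    @property
    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.depths()[: self.n_tips]
        h = d.max()
        if h == 0:
            return True
        return bool((h - d.min()) <= rtol * h)

    def _levels(self) -> np.ndarray:
        if self._nlevels is None:
            lv = np.zeros(self.n_nodes, dtype=np.int64)
            for v in self.preorder:
                p = int(self.parent[v])
                if p >= 0:
                    lv[v] = lv[p] + 1
            self._nlevels = lv
        return self._nlevels

    def mrca(self, nodes: Iterable[int]) -> int:
        lv = self._levels()
        it = iter(nodes)
        a = int(next(it))
        for b in it:
            b = int(b)
            while lv[a] > lv[b]:
                a = int(self.parent[a])
            while lv[b] > lv[a]:
                b = int(self.parent[b])
            while a != b:
                a = int(self.parent[a])
                b = int(self.parent[b])
        return a

    def patristic(self, u: int, v: int) -> float:
        d = self.depths()
        return float(d[u] + d[v] - 2.0 * d[self.mrca((u, v))])

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise KeyError(f"tip label not in tree: {label!r}") from None

    def ancestors(self, v: int) -> list[int]:
        out = []
        p = int(self.parent[v])
        while p >= 0:
            out.append(p)
            p = int(self.parent[p])
        return out

    # ------------------------------------------------------------------ #
    # conversion
    # ------------------------------------------------------------------ #
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        nodes = list(dtree.postorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        index: dict[int, int] = {}
        labels = []
        for i, nd in enumerate(tips):
            index[id(nd)] = i
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None:
                raise TreeStructureError("unlabelled tip in input tree")
            labels.append(str(lab))
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        for nd in nodes:
            v = index[id(nd)]
            if nd.parent_node is not None:
                parent[v] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise MissingBranchLengthError(
                        "tree has a branch without a length; all analyses need "
                        "time-calibrated branch lengths"
                    )
                blen[v] = float(nd.edge.length)
        return cls(parent, blen, labels)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)
        dnodes: dict[int, dendropy.Node] = {}
        for v in self.preorder:
            v = int(v)
            if v == self.root:
                nd = dtree.seed_node
            else:
                nd = dendropy.Node()
                dnodes[int(self.parent[v])].add_child(nd)
                nd.edge.length = float(self.blen[v])
            if v < self.n_tips:
                nd.taxon = tns.require_taxon(label=self.tip_labels[v])
            dnodes[v] = nd
        return dtree

    @classmethod
    def from_newick(cls, s: str) -> "TimeTree":
        dtree = dendropy.Tree.get(
            data=s, schema="newick", preserve_underscores=True, suppress_internal_node_taxa=True
        )
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        out = io.StringIO()
        self.to_dendropy().write(
            file=out, schema="newick", unquoted_underscores=True, suppress_rooting=True
        )
        return out.getvalue().strip()

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent, self.blen, self.tip_labels)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<TimeTree n_tips={self.n_tips} n_nodes={self.n_nodes} height={self.height:.4g}>"

    # ------------------------------------------------------------------ #
    # surgery
    # ------------------------------------------------------------------ #
    def _nested(self):
        """Bottom-up nested dict view used by the surgery methods."""
        nodes: list[dict | None] = [None] * self.n_nodes
        for v in self.postorder:
            v = int(v)
            d = {
                "orig": v,
                "blen": float(self.blen[v]),
                "children": [nodes[c] for c in self.children[v]],
            }
            if v < self.n_tips:
                d["label"] = self.tip_labels[v]
            nodes[v] = d
        return nodes[self.root]

    @classmethod
    def _from_nested(cls, root: dict) -> tuple["TimeTree", dict[int, int]]:
        tips: list[dict] = []
        internals: list[dict] = []

        def walk(node: dict) -> None:
            if not node["children"]:
                tips.append(node)
            else:
                for c in node["children"]:
                    walk(c)
                internals.append(node)

        walk(root)
        n = len(tips) + len(internals)
        newid: dict[int, dict] = {}
        for i, nd in enumerate(tips):
            nd["_new"] = i
        for j, nd in enumerate(internals):
            nd["_new"] = len(tips) + j
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        labels = [nd.get("label", f"tip{i}") for i, nd in enumerate(tips)]

        def wire(node: dict) -> None:
            for c in node["children"]:
                parent[c["_new"]] = node["_new"]
                blen[c["_new"]] = c["blen"]
                wire(c)

        wire(root)
        tree = cls(parent, blen, labels)
        idmap = {}
        for nd in tips + internals:
            if "orig" in nd:
                idmap[nd["orig"]] = nd["_new"]
        return tree, idmap

    def prune_to_tips(self, labels: Iterable[str]) -> tuple["TimeTree", dict[int, int]]:
        """Induced subtree on ``labels``.

        Internal nodes left with a single child are suppressed and their
        branch lengths summed, so root-to-tip depths and pairwise patristic
        distances among the kept tips are preserved exactly.  The original
        root is retained even if it ends up with a single child.

        Returns the pruned tree and a map from surviving original node ids to
        new node ids (suppressed nodes are absent from the map).
        """
        keep = set(labels)
        unknown = keep - set(self.tip_labels)
        if unknown:
            raise KeyError(f"labels not in tree: {sorted(unknown)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to prune to")

        def rec(node: dict) -> dict | None:
            if not node["children"]:
                return node if node.get("label") in keep else None
            kept = [c for c in (rec(c) for c in node["children"]) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                child["blen"] += node["blen"]
                return child
            node["children"] = kept
            return node

        nested = self._nested()
        kept_top = [c for c in (rec(c) for c in nested["children"]) if c is not None]
        if not kept_top:
            raise ValueError("no tips kept")
        nested["children"] = kept_top
        return self._from_nested(nested)

    def collapse_clade(self, node: int, label: str) -> tuple["TimeTree", dict[int, int]]:
        """Replace the clade rooted at ``node`` by a single tip.

        The new tip keeps the clade root's branch, i.e. it ends at the
        original crown-node depth of the collapsed group.
        """
        if node == self.root:
            raise ValueError("cannot collapse the whole tree")
        nested = self._nested()

        def rec(d: dict) -> None:
            for c in d["children"]:
                if c["orig"] == node:
                    c["children"] = []
                    c["label"] = label
                    c.pop("orig")  # identity changed: clade root -> tip
                else:
                    rec(c)

        rec(nested)
        return self._from_nested(nested)

    # ------------------------------------------------------------------ #
    # misc
    # ------------------------------------------------------------------ #
    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n_tips, self.n_nodes, dtype=np.int64)

    def tips_below(self, node: int) -> list[int]:
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(out)
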