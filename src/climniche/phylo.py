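"""Lightweight rooted-tree container used throughout the package.

Trees are inputs here (time-scaled, branch lengths in Ma); nothing in this
package infers topology or divergence times.  Newick parsing is delegated to
dendropy; internally a tree is flattened to parent-pointer arrays so that the
pruning, painting and moment recursions can run over plain index loops.

Node indexing convention: tips are ``0 .. n_tips-1`` in the order of
``tips``; internal nodes follow; the root is always the last index
(``n_nodes - 1``).  ``postorder`` lists every node child-before-parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylo", "read_newick"]


@dataclass
class Phylo:
    """Rooted binary tree with branch lengths, flattened to arrays.

    Attributes
    ----------
    tips : list[str]
        Tip labels, unique, in node-index order (tip ``i`` has node id ``i``).
    parent : np.ndarray
        ``parent[i]`` is the node id of ``i``'s parent; ``-1`` for the root.
    blen : np.ndarray
        Length of the branch subtending each node (0.0 for the root).
    """

    tips: list[str]
    parent: np.ndarray
    blen: np.ndarray
    children_order: list[list[int]] | None = None
    _children: list[list[int]] = field(init=False, repr=False)
    _postorder: np.ndarray = field(init=False, repr=False)
    _clades: list[np.ndarray] | None = field(init=False, repr=False, default=None)
    _mrca: np.ndarray | None = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=float)
        n = self.parent.size
        if len(set(self.tips)) != len(self.tips):
            raise ValueError("tip labels must be unique")
        if np.any(self.blen[: n - 1] < 0) or self.blen.size != n:
            raise ValueError("branch lengths must be >= 0 for all non-root nodes")
        if self.children_order is not None:
            children = [list(c) for c in self.children_order]
            for i, ch in enumerate(children):
                for c in ch:
                    if self.parent[c] != i:
                        raise ValueError("children_order inconsistent with parents")
        else:
            children = [[] for _ in range(n)]
            for i in range(n - 1):
                children[self.parent[i]].append(i)
        for i, ch in enumerate(children):
            if i >= self.n_tips and len(ch) != 2:
                raise ValueError(
                    f"node {i} has {len(ch)} children; only rooted binary trees "
                    "are accepted (resolve polytomies upstream)"
                )
        self._children = children
        # iterative postorder (children before parents)
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(children[v])
        self._postorder = np.array(order[::-1], dtype=np.int64)

    # -- basic structure ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self.parent.size - 1

    def children(self, node: int) -> list[int]:
        return self._children[node]

    @property
    def postorder(self) -> np.ndarray:
        return self._postorder

    @property
    def preorder(self) -> np.ndarray:
        return self._postorder[::-1]

    # -- derived structure (cached) ---------------------------------------
    def clade_tips(self, node: int) -> np.ndarray:
        """Tip indices descending from ``node`` (a tip is its own clade)."""
        if self._clades is None:
            clades: list[np.ndarray | None] = [None] * self.n_nodes
            for v in self._postorder:
                if v < self.n_tips:
                    clades[v] = np.array([v], dtype=np.int64)
                else:
                    clades[v] = np.concatenate([clades[c] for c in self._children[v]])
            self._clades = clades  # type: ignore[assignment]
        return self._clades[node]  # type: ignore[index]

    def mrca_matrix(self) -> np.ndarray:
        """``M[i, j]`` = node id of the most recent common ancestor of tips i, j.

        Built once per tree in O(n^2) by writing each internal node's id into
        the cross-blocks of its two child clades; reused by every covariance
        evaluation.
        """
        if self._mrca is None:
            n = self.n_tips
            M = np.empty((n, n), dtype=np.int64)
            M[np.diag_indices(n)] = np.arange(n)
            for v in self._postorder:
                if v < n:
                    continue
                c1, c2 = self._children[v]
                a, b = self.clade_tips(c1), self.clade_tips(c2)
                M[np.ix_(a, b)] = v
                M[np.ix_(b, a)] = v
            self._mrca = M
        return self._mrca

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.blen[v]
        return d

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self.node_depths()[: self.n_tips]
        return bool(np.ptp(depths) <= tol * max(1.0, depths.max()))

    # -- I/O ---------------------------------------------------------------
    def to_newick(self, internal_labels: dict[int, str] | None = None) -> str:
        """Deterministic Newick string (fixed float formatting).

        ``internal_labels`` optionally annotates internal nodes (e.g. with a
        reconstructed state) as node labels.
        """

        def fmt(v: int) -> str:
            if v < self.n_tips:
                return f"{self.tips[v]}:{self.blen[v]:.10g}"
            inner = ",".join(fmt(c) for c in self._children[v])
            lab = internal_labels.get(v, "") if internal_labels else ""
            tail = "" if v == self.root else f":{self.blen[v]:.10g}"
            return f"({inner}){lab}{tail}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Phylo":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as err:  # dendropy's reader errors are parser-specific
            if "Duplicate" in type(err).__name__ or "duplicate" in str(err).lower():
                raise ValueError("tip labels must be unique") from err
            raise
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylo":
        nodes = list(dtree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        labels = [nd.taxon.label if nd.taxon else (nd.label or "") for nd in tips]
        if any(not lab for lab in labels):
            raise ValueError("every tip must carry a label")
        # tips first, internals reversed so the root lands last and parents
        # always have larger ids than their children
        index = {id(nd): i for i, nd in enumerate(tips)}
        for j, nd in enumerate(reversed(internals)):
            index[id(nd)] = len(tips) + j
        n = len(tips) + len(internals)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        children_order: list[list[int]] = [[] for _ in range(n)]
        for nd in nodes:
            i = index[id(nd)]
            children_order[i] = [index[id(c)] for c in nd.child_nodes()]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(tips=labels, parent=parent, blen=blen,
                   children_order=children_order)


def read_newick(path: str) -> Phylo:
    """Read a rooted, binary, time-scaled tree from a Newick file."""
    dtree = dendropy.Tree.get(path=path, schema="newick")
    return Phylo.from_dendropy(dtree)
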