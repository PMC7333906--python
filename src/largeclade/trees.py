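"""Ultrametric tree container and Newick/NEXUS interchange.

Trees are stored as flat integer arrays (parent pointers, child pairs) with
one age per node, measured in Myr before present: tips sit at age 0 and the
root age is the tree height.  This array layout is what the MCMC kernel and
the simulators operate on directly; :mod:`dendropy` handles serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["UltrametricTree"]

NO_NODE = -1


@dataclass
class UltrametricTree:
    """Rooted binary ultrametric tree with node ages in Myr before present.

    Node ids ``0 .. n_tips-1`` are tips (age 0, labelled by ``tip_labels``);
    ids ``n_tips .. 2*n_tips-2`` are internal nodes.  ``parent[root] == -1``.

    Parameters
    ----------
    parent
        ``(M,)`` int array, parent node id of each node (-1 at the root).
    children
        ``(M, 2)`` int array, the two children of each internal node
        (-1, -1 for tips).
    ages
        ``(M,)`` float array of node ages, Myr before present.
    tip_labels
        Tip names, in node-id order.
    origin_age
        Optional stem origin (Myr) for trees grown from a single founder;
        the root node then marks the first branching, not the origin.
    """

    parent: np.ndarray
    children: np.ndarray
    ages: np.ndarray
    tip_labels: list[str]
    origin_age: float | None = None
    _postorder: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.children = np.asarray(self.children, dtype=np.int64)
        self.ages = np.asarray(self.ages, dtype=np.float64)
        self.validate()

    # -- basic structure ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == NO_NODE)[0])

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def branch_length(self, node: int) -> float:
        """Duration (Myr) of the branch subtending ``node``; 0 at the root."""
        p = self.parent[node]
        if p == NO_NODE:
            return 0.0
        return float(self.ages[p] - self.ages[node])

    def internal_ages(self, include_root: bool = True) -> np.ndarray:
        """Ages of internal nodes, sorted descending (root first)."""
        ages = self.ages[self.n_tips :]
        ages = np.sort(ages)[::-1]
        return ages if include_root else ages[1:]

    def postorder_internal(self) -> np.ndarray:
        """Internal node ids in postorder (children before parents)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            seen: list[int] = []
            while stack:
                v = stack.pop()
                if v >= self.n_tips:
                    seen.append(v)
                    stack.extend(int(c) for c in self.children[v])
            order = seen[::-1]
            self._postorder = np.asarray(order, dtype=np.int64)
        return self._postorder

    def total_branch_length(self) -> float:
        p = self.parent
        has_parent = p != NO_NODE
        return float(np.sum(self.ages[p[has_parent]] - self.ages[has_parent]))

    def validate(self) -> None:
        n = self.n_tips
        M = self.n_nodes
        if M != 2 * n - 1:
            raise ValueError(f"expected {2 * n - 1} nodes for {n} tips, got {M}")
        if np.count_nonzero(self.parent == NO_NODE) != 1:
            raise ValueError("tree must have exactly one root")
        if np.any(np.abs(self.ages[:n]) > 1e-9):
            raise ValueError("tips must sit at age 0")
        for v in range(n, M):
            c0, c1 = self.children[v]
            if c0 == NO_NODE or c1 == NO_NODE:
                raise ValueError(f"internal node {v} lacks two children")
            if self.ages[v] < self.ages[c0] or self.ages[v] < self.ages[c1]:
                raise ValueError(f"node {v} younger than a child")

    # -- interchange -------------------------------------------------------
    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace(self.tip_labels)
        tree = dendropy.Tree(taxon_namespace=tns)
        nodes = {}
        for v in range(self.n_nodes):
            nd = dendropy.Node()
            if self.is_tip(v):
                nd.taxon = tns.get_taxon(self.tip_labels[v])
            nodes[v] = nd
        for v in range(self.n_tips, self.n_nodes):
            for c in self.children[v]:
                child = nodes[int(c)]
                child.edge.length = float(self.ages[v] - self.ages[int(c)])
                nodes[v].add_child(child)
        root = nodes[self.root]
        if self.origin_age is not None:
            root.edge.length = float(self.origin_age - self.root_age)
        tree.seed_node = root
        return tree

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, tol: float = 1e-6) -> "UltrametricTree":
        """Build from a rooted binary dendropy tree with ultrametric branch lengths."""
        leaves = [lf for lf in tree.leaf_node_iter()]
        n = len(leaves)
        tip_labels = [lf.taxon.label if lf.taxon else f"t{i}" for i, lf in enumerate(leaves)]
        ids: dict[dendropy.Node, int] = {lf: i for i, lf in enumerate(leaves)}
        next_id = n
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            if len(nd.child_nodes()) != 2:
                raise ValueError("tree must be strictly bifurcating")
            ids[nd] = next_id
            next_id += 1
        M = next_id
        parent = np.full(M, NO_NODE, dtype=np.int64)
        children = np.full((M, 2), NO_NODE, dtype=np.int64)
        ages = np.zeros(M)
        # node depth from root, then convert to age = height - depth
        depth = {tree.seed_node: 0.0}
        for nd in tree.preorder_node_iter():
            if nd is not tree.seed_node:
                depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
        height = max(depth[lf] for lf in leaves)
        tip_depths = np.array([depth[lf] for lf in leaves])
        if np.any(np.abs(tip_depths - height) > tol * max(height, 1.0)):
            raise ValueError("tree is not ultrametric")
        for nd, v in ids.items():
            ages[v] = 0.0 if nd.is_leaf() else height - depth[nd]
            if nd is not tree.seed_node:
                parent[v] = ids[nd.parent_node]
            if not nd.is_leaf():
                c0, c1 = nd.child_nodes()
                children[v] = (ids[c0], ids[c1])
        origin = None
        if tree.seed_node.edge.length:
            origin = height + tree.seed_node.edge.length
        return cls(parent, children, ages, tip_labels, origin_age=origin)

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "UltrametricTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def write(self, path: str, schema: str = "newick") -> None:
        """Write to ``path`` as ``"newick"`` or ``"nexus"``."""
        self.to_dendropy().write(path=path, schema=schema)

    @classmethod
    def read(cls, path: str, schema: str = "newick") -> "UltrametricTree":
        return cls.from_dendropy(dendropy.Tree.get(path=path, schema=schema))
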