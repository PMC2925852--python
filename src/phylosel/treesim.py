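"""Guide trees: array-backed phylogenies and the study's tree generators.

Two kinds of guide tree are used.  Ultrametric trees are drawn from a
tip-count-conditioned birth-death process and rescaled to a stated height
(expected substitutions per site from root to tip).  One non-clock tree mixes
short and long branches deterministically: its internal edges carry lengths
10**(2x/18 - 3) for a random permutation of x = 0..18 and its external edges
10**(2x/21 - 3) for x = 0..21.
"""

from __future__ import annotations

import random
from typing import Sequence

import numpy as np
import dendropy
from dendropy.simulate import treesim as _dtreesim

__all__ = [
    "PhyloTree",
    "simulate_birth_death_tree",
    "scale_to_height",
    "build_nonclock_tree",
]


class PhyloTree:
    """Binary phylogeny stored as parent/child arrays.

    Node ids: tips are ``0 .. ntips-1`` in the order of ``taxa``; internal
    nodes follow; the root is the node with parent ``-1``.  ``edge_length[v]``
    is the length of the edge above node ``v`` (undefined for the root).  A
    rooted binary tree has a bifurcating root; an unrooted tree is stored
    rooted at an internal node with three children.
    """

    def __init__(self, taxa: Sequence[str], parent: np.ndarray,
                 edge_length: np.ndarray, rooted: bool = True):
        self.taxa = list(taxa)
        self.parent = np.asarray(parent, dtype=int)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.rooted = rooted
        self.ntips = len(self.taxa)
        self.n_nodes = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        self._check_binary()
        self.postorder = self._postorder()

    # -- construction -----------------------------------------------------

    def _check_binary(self) -> None:
        for v, ch in enumerate(self.children):
            n = len(ch)
            if v < self.ntips:
                if n != 0:
                    raise ValueError("tip node with children")
            elif v == self.root:
                want = 2 if self.rooted else 3
                if n != want:
                    raise ValueError(
                        f"root must have {want} children, found {n}")
            elif n != 2:
                raise ValueError("internal node must be bifurcating")

    def _postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, rooted: bool = True) -> "PhyloTree":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaves = [lf for lf in tree.leaf_node_iter()]
        taxa = sorted(lf.taxon.label for lf in leaves)
        index = {label: i for i, label in enumerate(taxa)}
        nodes = [nd for nd in tree.postorder_node_iter()]
        internal = [nd for nd in nodes if not nd.is_leaf()]
        ids: dict = {}
        for nd in nodes:
            if nd.is_leaf():
                ids[nd] = index[nd.taxon.label]
        for k, nd in enumerate(internal):
            ids[nd] = len(taxa) + k
        n = len(taxa) + len(internal)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        for nd in nodes:
            if nd.parent_node is not None:
                parent[ids[nd]] = ids[nd.parent_node]
                lengths[ids[nd]] = nd.edge.length or 0.0
        return cls(taxa, parent, lengths, rooted=rooted)

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        nchild = len(tree.seed_node.child_nodes())
        if rooted is None:
            rooted = nchild == 2
        return cls.from_dendropy(tree, rooted=rooted)

    def to_dendropy(self) -> dendropy.Tree:
        taxon_ns = dendropy.TaxonNamespace(self.taxa)
        tree = dendropy.Tree(taxon_namespace=taxon_ns)
        nodes = {}
        for v in self.postorder:
            nd = dendropy.Node()
            if v < self.ntips:
                nd.taxon = taxon_ns.get_taxon(self.taxa[v])
            if v != self.root:
                nd.edge.length = float(self.edge_length[v])
            nodes[v] = nd
        for v in self.postorder:
            for c in self.children[v]:
                nodes[v].add_child(nodes[c])
        tree.seed_node = nodes[self.root]
        tree.is_rooted = self.rooted
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True).strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.taxa, self.parent.copy(),
                         self.edge_length.copy(), rooted=self.rooted)

    # -- queries ----------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def edge_nodes(self) -> np.ndarray:
        """Node ids owning an edge (all but the root), in node-id order.

        This fixed ordering is the shared branch-length indexing used by all
        model fits on one topology.
        """
        return np.array([v for v in range(self.n_nodes) if v != self.root])

    def branch_lengths(self) -> np.ndarray:
        return self.edge_length[self.edge_nodes]

    def set_branch_lengths(self, values: np.ndarray) -> None:
        self.edge_length[self.edge_nodes] = values

    def tip_depths(self) -> np.ndarray:
        depth = np.zeros(self.n_nodes)
        for v in reversed(self.postorder):
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.edge_length[v]
        return depth[: self.ntips]

    def height(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.tip_depths()
        return bool(np.ptp(d) <= tol * max(1.0, d.max()))

    def total_length(self) -> float:
        return float(self.edge_length[self.edge_nodes].sum())

    def internal_edge_nodes(self) -> np.ndarray:
        return np.array([v for v in self.edge_nodes if v >= self.ntips])

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions as frozensets of taxon labels (one side)."""
        below: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for v in self.postorder:
            if v < self.ntips:
                below[v] = {v}
            else:
                for c in self.children[v]:
                    below[v] |= below[c]
        out = set()
        full = set(range(self.ntips))
        for v in self.internal_edge_nodes():
            side = below[v]
            if len(side) < 2 or len(side) > self.ntips - 2:
                continue
            canon = min(side, full - side, key=lambda s: sorted(s))
            out.add(frozenset(self.taxa[i] for i in canon))
        return out

    def unroot(self) -> "PhyloTree":
        """Collapse a bifurcating root into a trifurcation (2n-3 edges)."""
        if not self.rooted:
            return self.copy()
        c1, c2 = self.children[self.root]
        # fold the root into whichever child is internal
        keep, other = (c1, c2) if c1 >= self.ntips else (c2, c1)
        if keep < self.ntips:
            raise ValueError("cannot unroot a two-taxon tree")
        parent = self.parent.copy()
        lengths = self.edge_length.copy()
        parent[other] = keep
        lengths[other] = lengths[c1] + lengths[c2]
        parent[keep] = -1
        # drop the old root node by remapping ids
        old = [v for v in range(self.n_nodes) if v != self.root]
        remap = {v: k for k, v in enumerate(old)}
        new_parent = np.array([remap[parent[v]] if parent[v] >= 0 else -1
                               for v in old])
        new_lengths = np.array([lengths[v] for v in old])
        return PhyloTree(self.taxa, new_parent, new_lengths, rooted=False)


def simulate_birth_death_tree(ntaxa: int, birth: float = 0.1,
                              death: float = 0.1, sampling: float = 1.0,
                              seed: int = 0, max_retries: int = 1000) -> PhyloTree:
    """Rooted ultrametric tree conditioned on a fixed number of extant tips.

    A constant-rate birth-death process is grown until ``ntaxa`` extant
    lineages exist (retrying on extinction); extinct lineages are pruned.
    ``sampling`` < 1 simulates ``ntaxa / sampling`` tips and retains a random
    subset of ``ntaxa``.
    """
    if ntaxa < 2:
        raise ValueError("need at least two taxa")
    if birth < 0 or death < 0 or not (0 < sampling <= 1):
        raise ValueError("invalid birth-death parameters")
    rng = random.Random(seed)
    grow_to = int(round(ntaxa / sampling))
    tree = None
    for _ in range(max_retries):
        try:
            tree = _dtreesim.birth_death_tree(
                birth_rate=birth, death_rate=death, num_extant_tips=grow_to,
                rng=rng, repeat_until_success=False)
            break
        except Exception:
            continue
    if tree is None:
        raise RuntimeError(
            f"birth-death process went extinct {max_retries} times before "
            f"reaching {grow_to} tips")
    if grow_to > ntaxa:
        leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
        keep = rng.sample(leaves, ntaxa)
        tree.retain_taxa([lf.taxon for lf in keep])
        tree.suppress_unifurcations()
    out = PhyloTree.from_dendropy(tree, rooted=True)
    out = _relabel(out)
    return out


def _relabel(tree: PhyloTree) -> PhyloTree:
    """Rename taxa to t1..tN (keeping tip-id order)."""
    tree = tree.copy()
    tree.taxa = [f"t{i + 1}" for i in range(tree.ntips)]
    return tree


def scale_to_height(tree: PhyloTree, height: float) -> PhyloTree:
    """Rescale all branch lengths by one factor so the tree height is ``height``."""
    h = tree.height()
    if h <= 0:
        raise ValueError("input tree has zero height")
    if height <= 0:
        raise ValueError("target height must be positive")
    out = tree.copy()
    out.edge_length = out.edge_length * (height / h)
    return out


def build_nonclock_tree(seed: int = 0, topology: PhyloTree | None = None,
                        ntaxa: int = 22) -> PhyloTree:
    """The study's non-clock tree: formula-defined branch lengths on an
    unrooted binary topology of 22 taxa.

    Internal edges receive lengths 10**(2x/18 - 3) for a random permutation
    of labels x = 0..18; external edges 10**(2x/21 - 3) for x = 0..21.  The
    default topology is drawn from the birth-death sampler (topology only).
    """
    rng = np.random.default_rng(seed)
    if topology is None:
        topology = simulate_birth_death_tree(ntaxa, seed=seed)
    if topology.ntips != ntaxa:
        raise ValueError(f"topology must have {ntaxa} taxa")
    tree = topology.unroot() if topology.rooted else topology.copy()
    internal = tree.internal_edge_nodes()
    external = np.arange(tree.ntips)
    n_int, n_ext = len(internal), len(external)
    x_int = rng.permutation(n_int)
    x_ext = rng.permutation(n_ext)
    tree.edge_length[internal] = 10.0 ** (2.0 * x_int / (n_int - 1) - 3.0)
    tree.edge_length[external] = 10.0 ** (2.0 * x_ext / (n_ext - 1) - 3.0)
    return tree
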