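"""Rooted phylogenies with branch lengths.

The in-memory representation is a flat array form (parent pointers,
child lists, per-node edge lengths, post-order traversal) so that the
likelihood machinery in :mod:`sodalake.mk_transition` can evaluate
Felsenstein pruning without touching a node-object API in the hot loop.
Newick parsing and serialization are delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import InvalidTreeError

__all__ = ["Phylogeny", "read_newick", "write_newick"]


@dataclass
class Phylogeny:
    """A rooted tree in flat-array form.

    Nodes ``0 .. n_tips-1`` are the tips, in the order of ``tip_labels``;
    the remaining ids are internal nodes.  ``edge_length[i]`` is the length
    of the branch above node ``i`` (0 for the root).
    """

    tip_labels: list[str]
    parent: np.ndarray
    children: list[list[int]]
    edge_length: np.ndarray
    root: int
    postorder_internal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.edge_length = np.asarray(self.edge_length, dtype=np.float64)
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise InvalidTreeError("duplicate tip labels")
        if np.any(self.edge_length < 0) or not np.all(np.isfinite(self.edge_length)):
            raise InvalidTreeError("branch lengths must be finite and non-negative")
        if self.postorder_internal is None:
            self.postorder_internal = _postorder_internal(self.children, self.root)

    # ------------------------------------------------------------------ basics
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def branch_lengths(self) -> np.ndarray:
        """Lengths of all true branches (every node except the root)."""
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return self.edge_length[mask]

    def mean_branch_length(self) -> float:
        return float(self.branch_lengths().mean())

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            tip_labels=list(self.tip_labels),
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            edge_length=self.edge_length.copy(),
            root=self.root,
            postorder_internal=self.postorder_internal.copy(),
        )

    # ------------------------------------------------------------------ scaling
    def scaled(self, target_mean: float) -> "Phylogeny":
        """Return a copy rescaled so the mean branch length equals ``target_mean``.

        Every branch is multiplied by the single constant
        ``target_mean / current_mean``, preserving all length ratios.
        """
        if target_mean <= 0:
            raise InvalidTreeError("target mean branch length must be positive")
        current = self.mean_branch_length()
        if current == 0:
            raise InvalidTreeError("cannot scale a tree whose branch lengths are all zero")
        out = self.copy()
        out.edge_length = self.edge_length * (target_mean / current)
        out.edge_length[self.root] = 0.0
        return out

    # ------------------------------------------------------------------ dendropy bridge
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        leaves = [nd for nd in tree.leaf_node_iter()]
        for nd in leaves:
            if nd.taxon is None or not nd.taxon.label:
                raise InvalidTreeError("every leaf must carry a label")
        internals = [nd for nd in tree.preorder_internal_node_iter()]
        n_tips = len(leaves)
        index: dict[dendropy.Node, int] = {}
        tip_labels = []
        for i, nd in enumerate(leaves):
            index[nd] = i
            tip_labels.append(str(nd.taxon.label))
        for j, nd in enumerate(internals):
            index[nd] = n_tips + j
        n_nodes = n_tips + len(internals)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        edge_length = np.zeros(n_nodes, dtype=np.float64)
        root = index[tree.seed_node]
        for nd, i in index.items():
            if nd.parent_node is not None:
                p = index[nd.parent_node]
                parent[i] = p
                children[p].append(i)
                bl = nd.edge.length
                if bl is None:
                    raise InvalidTreeError("branch lengths are required on every edge")
                if bl < 0:
                    raise InvalidTreeError("negative branch length")
                edge_length[i] = float(bl)
        return cls(tip_labels, parent, children, edge_length, root)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lab in enumerate(self.tip_labels):
            nodes[i].taxon = taxa.get_taxon(lab)
        for i in range(self.n_nodes):
            if i != self.root:
                nodes[self.parent[i]].add_child(nodes[i])
                nodes[i].edge.length = float(self.edge_length[i])
        tree.seed_node = nodes[self.root]
        tree.is_rooted = True
        return tree

    # ------------------------------------------------------------------ newick
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse-error types
            raise InvalidTreeError(f"newick parse failure: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
            unquoted_underscores=True,
        ).strip()


def _postorder_internal(children: list[list[int]], root: int) -> np.ndarray:
    """Internal node ids, children before parents (iterative post-order)."""
    order: list[int] = []
    stack = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if not children[node]:
            continue
        if expanded:
            order.append(node)
        else:
            stack.append((node, True))
            for c in children[node]:
                stack.append((c, False))
    return np.asarray(order, dtype=np.int64)


def read_newick(path) -> Phylogeny:
    """Read a rooted, branch-lengthed tree from a newick file."""
    with open(path) as fh:
        text = fh.read()
    # tolerate '#'-prefixed metadata comment lines written by the pipeline
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    return Phylogeny.from_newick("\n".join(lines))


def write_newick(tree: Phylogeny, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(tree.to_newick() + "\n")


def scale_tree(tree: Phylogeny, target_mean: float = 0.1) -> Phylogeny:
    """Rescale ``tree`` so its mean branch length equals ``target_mean``.

    Rate estimates from a continuous-time Markov model are confounded with
    the overall time scale of the tree; fixing the mean branch length (0.1
    by convention) keeps rates in a numerically comfortable range.
    """
    return tree.scaled(target_mean)


def yule_tree(n_tips: int, birth_rate: float, seed: int) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` extant tips.

    Tips are labelled ``sp0001 .. spNNNN``.  A Yule process is the simplest
    branching model that produces rooted binary trees with positive branch
    lengths and known expectations (e.g. the root-to-tip number of
    bifurcations grows like log n), which is all the downstream machinery
    requires of a stand-in species tree.
    """
    import random as _random

    from dendropy.simulate import treesim

    if n_tips < 2:
        raise InvalidTreeError("a tree needs at least 2 tips")
    if birth_rate <= 0 or not math.isfinite(birth_rate):
        raise InvalidTreeError("birth rate must be positive and finite")
    rng = _random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=float(birth_rate),
        death_rate=0.0,
        num_extant_tips=int(n_tips),
        rng=rng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
    phy = Phylogeny.from_dendropy(tree)
    # guard: birth_death_tree can emit zero-length terminal edges at the
    # stopping time; nudge them to a tiny positive value so downstream
    # log-scaling never divides by zero
    zero = phy.edge_length == 0
    zero[phy.root] = False
    if zero.any():
        phy.edge_length[zero] = 1e-9
    return phy
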