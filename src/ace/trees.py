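"""Rooted species/gene trees with stable integer indexing.

Trees are stored as flat postorder arrays (parent pointers, children
lists, branch lengths, supports) so that the dynamic programs in
:mod:`ace.reconcile` can run over plain integer indices.  Newick parsing
and serialisation go through dendropy.

Newick dialect: internal node labels are read as *names* unless they
parse as a number in [0, 100], in which case they are taken to be
bipartition supports (the common IQ-TREE/FastTree convention).  Internal
nodes without a name are assigned the deterministic name ``N<postorder
index>``, which gives stable keys for event tables.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Tree", "SpeciesTree", "read_species_tree", "write_species_tree"]


def _label_is_support(label: str) -> bool:
    try:
        v = float(label)
    except ValueError:
        return False
    return 0.0 <= v <= 100.0


@dataclass
class Tree:
    """A rooted tree in postorder array form.

    Node ``i`` satisfies ``i < parent[i]`` for every non-root node; the
    root is the last index.  ``children[i]`` preserves input order.
    """

    names: list[str]
    parent: np.ndarray          # int, -1 at root
    children: list[list[int]]
    lengths: np.ndarray         # float, branch above each node (root: 0)
    supports: np.ndarray        # float, NaN when absent
    auto_named: np.ndarray      # bool, True if name was generated
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {n: i for i, n in enumerate(self.names)}
        if len(self.index) != len(self.names):
            dupes = {n for n in self.names if self.names.count(n) > 1}
            raise ValueError(f"duplicate node names: {sorted(dupes)}")
        if np.any(self.lengths < 0):
            raise ValueError("negative branch length")

    # -- basic structure ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    def postorder(self) -> range:
        return range(self.n_nodes)

    def subtree(self, i: int) -> list[int]:
        """Node indices in the clade rooted at ``i`` (postorder)."""
        out: list[int] = []

        def walk(j: int) -> None:
            for c in self.children[j]:
                walk(c)
            out.append(j)

        walk(i)
        return out

    def leaf_set(self, i: int) -> set[int]:
        return {j for j in self.subtree(i) if self.is_leaf(j)}

    def ancestors(self, i: int) -> list[int]:
        """Strict ancestors of ``i``, nearest first."""
        out = []
        j = int(self.parent[i])
        while j != -1:
            out.append(j)
            j = int(self.parent[j])
        return out

    def is_ancestor(self, a: int, d: int) -> bool:
        """True if ``a`` is a strict ancestor of ``d``."""
        j = int(self.parent[d])
        while j != -1:
            if j == a:
                return True
            j = int(self.parent[j])
        return False

    def comparable(self, a: int, b: int) -> bool:
        """True if one node is an ancestor of (or equal to) the other."""
        return a == b or self.is_ancestor(a, b) or self.is_ancestor(b, a)

    def mrca(self, a: int, b: int) -> int:
        anc = {a} | set(self.ancestors(a))
        j = b
        while j not in anc:
            j = int(self.parent[j])
        return j

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (sum of branch lengths)."""
        d = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 2, -1, -1):
            d[i] = d[int(self.parent[i])] + self.lengths[i]
        return d

    # -- construction ---------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Tree":
        nodes = list(tree.postorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        names: list[str] = [""] * n
        parent = np.full(n, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        lengths = np.zeros(n)
        supports = np.full(n, np.nan)
        auto = np.zeros(n, dtype=bool)
        seen_leaves: set[str] = set()
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = idx[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
            if nd.edge.length is not None:
                lengths[i] = float(nd.edge.length)
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if nd.is_leaf():
                if label is None:
                    raise ValueError("unnamed leaf")
                if label in seen_leaves:
                    raise ValueError(f"duplicate leaf name: {label!r}")
                seen_leaves.add(label)
                names[i] = label
            else:
                if label is None or label == "":
                    names[i] = f"N{i}"
                    auto[i] = True
                elif _label_is_support(label):
                    supports[i] = float(label)
                    names[i] = f"N{i}"
                    auto[i] = True
                else:
                    names[i] = label
        # children were appended child-after-parent? postorder appends in
        # traversal order, which preserves the original child order.
        return cls(names, parent, children, lengths, supports, auto)

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except dendropy.dataio.newickreader.NewickReader\
                .NewickReaderDuplicateTaxonError as e:
            raise ValueError(f"duplicate leaf name: {e}") from e
        return cls.from_dendropy(tree)

    @classmethod
    def from_file(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- serialisation --------------------------------------------------
    def _node_newick(self, i: int, with_lengths: bool) -> str:
        if self.is_leaf(i):
            lab = self.names[i]
        else:
            inner = ",".join(
                self._node_newick(c, with_lengths) for c in self.children[i]
            )
            if self.auto_named[i] and not np.isnan(self.supports[i]):
                lab = f"({inner}){self.supports[i]:g}"
            elif self.auto_named[i]:
                lab = f"({inner})"
            else:
                lab = f"({inner}){self.names[i]}"
        if with_lengths and self.parent[i] != -1:
            lab += f":{self.lengths[i]:.10g}"
        return lab

    def to_newick(self, with_lengths: bool = True) -> str:
        return self._node_newick(self.root, with_lengths) + ";"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- editing --------------------------------------------------------
    def keep_leaves(self, keep: set[str]) -> "Tree":
        """Restriction of the tree to a subset of its leaves.

        Unary internal nodes created by the pruning are suppressed and
        their branch lengths summed; named internal nodes keep their
        names where they survive.
        """
        drop = set(self.leaf_names) - set(keep)
        if not drop:
            return self
        dtree = dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        taxa = [t for t in dtree.taxon_namespace if t.label in keep]
        dtree.retain_taxa(taxa)
        dtree.purge_taxon_namespace()
        buf = _io.StringIO()
        dtree.write(file=buf, schema="newick", suppress_rooting=True,
                    unquoted_underscores=True)
        return Tree.from_newick(buf.getvalue())


# A species tree is structurally identical; the alias keeps call sites
# self-documenting (leaf names are genome identifiers, internal names are
# ancestor labels used as EventTable keys).
SpeciesTree = Tree


def read_species_tree(path) -> Tree:
    """Read a rooted Newick species tree; see module docstring for dialect."""
    return Tree.from_file(path)


def write_species_tree(tree: Tree, path) -> None:
    tree.to_file(path)
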