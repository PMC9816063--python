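"""Rule-based identification of HGT donor lineages from homolog trees.

Gene families inferred to have originated inside the query group (here,
Chlamydiae) are screened against taxonomy-labeled homolog trees: query
clades are located, outlier long branches pruned, a tractable subtree
around each query clade selected, an outgroup sampled, and the donor
lineage read off as the taxonomy shared by the clades sister to and
subtending ("nested") the query clade at a chosen consensus level.

Tip labels follow ``<id>|<domain>|<superphylum>|<phylum>|<flag>`` with
``flag`` = 1 for query-group tips; empty taxonomy fields mean the rank
is unknown.  Internal node labels are bipartition supports (0-100 or
0-1 scales are both accepted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Alignment
from .trees import Tree

__all__ = [
    "LabeledHomologTree", "DonorCall",
    "prune_long_branches", "coverage_filter", "find_query_clades",
    "select_subtree", "sample_outgroup", "classify_donor",
]

RANKS = ("domain", "superphylum", "phylum")


@dataclass
class LabeledHomologTree:
    tree: Tree
    query: set[str]                      # tip names in the query group
    taxonomy: dict[str, tuple[str, str, str]]  # tip -> (dom, sup, phy)

    @classmethod
    def from_newick(cls, text: str) -> "LabeledHomologTree":
        raw = Tree.from_newick(text)
        query: set[str] = set()
        taxonomy: dict[str, tuple[str, str, str]] = {}
        names = list(raw.names)
        for i in raw.leaves:
            parts = raw.names[i].split("|")
            if len(parts) != 5:
                raise ValueError(f"bad tip label: {raw.names[i]!r}")
            tid, dom, sup, phy, flag = parts
            names[i] = tid
            taxonomy[tid] = (dom, sup, phy)
            if flag.strip() == "1":
                query.add(tid)
        relabeled = Tree(names, raw.parent, raw.children, raw.lengths,
                         raw.supports, raw.auto_named)
        return cls(relabeled, query, taxonomy)

    @classmethod
    def from_file(cls, path) -> "LabeledHomologTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        names = list(self.tree.names)
        for i in self.tree.leaves:
            tid = names[i]
            dom, sup, phy = self.taxonomy.get(tid, ("", "", ""))
            flag = "1" if tid in self.query else "0"
            names[i] = f"{tid}|{dom}|{sup}|{phy}|{flag}"
        labeled = Tree(names, self.tree.parent, self.tree.children,
                       self.tree.lengths, self.tree.supports,
                       self.tree.auto_named)
        return labeled.to_newick()

    def restrict(self, tips: set[str]) -> "LabeledHomologTree":
        sub = self.tree.keep_leaves(tips)
        return LabeledHomologTree(
            sub, self.query & tips,
            {t: self.taxonomy[t] for t in tips if t in self.taxonomy})

    def query_tips(self, node: int) -> set[str]:
        return {self.tree.names[i] for i in self.tree.leaf_set(node)} \
            & self.query

    def support(self, node: int) -> float:
        """Support of an internal node normalised to the 0-1 scale."""
        s = self.tree.supports[node]
        if np.isnan(s):
            return np.nan
        return s / 100.0 if s > 1.0 else float(s)


@dataclass
class DonorCall:
    family: str
    clade: int                 # postorder index of the query clade
    status: str                # donor-assigned | unresolved | de-novo-candidate
    label: str = ""
    rank: str = ""
    level: float = 0.75
    fraction: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if (self.status == "donor-assigned") != bool(self.label):
            raise ValueError("label must be set iff status is donor-assigned")


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def prune_long_branches(lt: LabeledHomologTree
                        ) -> tuple[LabeledHomologTree, list[str]]:
    """Remove tips with outlier terminal branch lengths.

    Outliers exceed Q3 + 1.5*IQR of the terminal lengths (strictly;
    quartiles by linear interpolation).  Single pass: the threshold is
    computed once from the input tree.
    """
    tree = lt.tree
    tips = tree.leaves
    if len(tips) < 4:
        raise ValueError("need at least 4 tips to assess outliers")
    lengths = np.array([tree.lengths[i] for i in tips])
    q1, q3 = np.percentile(lengths, [25, 75])
    threshold = q3 + 1.5 * (q3 - q1)
    removed = [tree.names[i] for i, l in zip(tips, lengths) if l > threshold]
    if not removed:
        return lt, []
    keep = {tree.names[i] for i in tips} - set(removed)
    return lt.restrict(keep), removed


def coverage_filter(aln: Alignment, min_fraction: float = 0.4) -> list[str]:
    """Sequences covering >= ``min_fraction`` of the trimmed alignment."""
    if aln.n_sites == 0:
        raise ValueError("zero-length alignment")
    codes = aln.residue_codes()
    cover = (codes >= 0).sum(axis=1) / aln.n_sites
    return [tid for tid, c in zip(aln.ids, cover) if c >= min_fraction]


# ---------------------------------------------------------------------------
# Clade selection
# ---------------------------------------------------------------------------

def find_query_clades(lt: LabeledHomologTree, max_clades: int = 3,
                      min_fraction: float = 0.25,
                      min_query: int = 2) -> list[int]:
    """Up to ``max_clades`` disjoint clades rich in query tips.

    A clade qualifies with >= ``min_fraction`` query tips (inclusive)
    and at least ``min_query`` of them.  Candidates are ranked by query
    count (desc), clade size (asc), then postorder index; overlapping
    (nested) candidates are resolved in that order.
    """
    tree = lt.tree
    cand = []
    for i in range(tree.n_nodes):
        if tree.is_leaf(i):
            continue
        tips = {tree.names[j] for j in tree.leaf_set(i)}
        nq = len(tips & lt.query)
        if nq >= min_query and nq / len(tips) >= min_fraction:
            cand.append((i, nq, len(tips)))
    cand.sort(key=lambda t: (-t[1], t[2], t[0]))
    chosen: list[int] = []
    for i, _, _ in cand:
        if len(chosen) == max_clades:
            break
        if all(not tree.comparable(i, j) for j in chosen):
            chosen.append(i)
    return chosen


def _steps_to_mrca(tree: Tree, a: int, b: int) -> int:
    """Edges from node ``a`` up to the most recent common ancestor with ``b``."""
    m = tree.mrca(a, b)
    steps, j = 0, a
    while j != m:
        j = int(tree.parent[j])
        steps += 1
    return steps


def select_subtree(lt: LabeledHomologTree, clade: int,
                   min_extra: int = 150, max_extra: int = 400,
                   min_steps: int = 3, min_support: float = 0.7
                   ) -> LabeledHomologTree:
    """Tractable subtree around a query clade for ML re-analysis.

    Walks rootward at least ``min_steps`` ancestors from the clade and
    accepts the first node carrying ``min_extra``-``max_extra``
    non-clade tips with support >= ``min_support``.  An oversized
    candidate is thinned by discarding distant clades (support >=
    ``min_support``, >= 5 tips, >= 6 edges from their root to the
    common ancestor with the query clade) until it fits.  If the whole
    tree holds fewer than ``min_extra`` extra tips it is returned
    unchanged.
    """
    tree = lt.tree
    clade_tips = {tree.names[i] for i in tree.leaf_set(clade)}
    all_tips = {tree.names[i] for i in tree.leaves}
    if len(all_tips - clade_tips) < min_extra:
        return lt
    anc = tree.ancestors(clade)
    for depth, node in enumerate(anc, start=1):
        if depth < min_steps:
            continue
        sup = lt.support(node)
        if node != tree.root and not np.isnan(sup) and sup < min_support:
            continue
        tips = {tree.names[i] for i in tree.leaf_set(node)}
        extra = len(tips) - len(clade_tips)
        if extra < min_extra:
            continue
        if extra <= max_extra:
            return lt.restrict(tips)
        # oversized: thin distant well-supported clades
        keep = set(tips)
        removable = []
        for j in tree.subtree(node):
            if tree.is_leaf(j) or tree.comparable(j, clade):
                continue
            supj = lt.support(j)
            nt = len(tree.leaf_set(j))
            if (not np.isnan(supj) and supj >= min_support and nt >= 5
                    and _steps_to_mrca(tree, j, clade) >= 6):
                removable.append((nt, j))
        removable.sort(reverse=True)  # drop the largest distant clades first
        for nt, j in removable:
            if len(keep) - len(clade_tips) <= max_extra:
                break
            jt = {tree.names[i] for i in tree.leaf_set(j)}
            if jt <= keep and len(keep) - len(jt) >= len(clade_tips) + min_extra:
                keep -= jt
        if len(keep) - len(clade_tips) <= max_extra:
            return lt.restrict(keep)
    return lt  # fall back to the whole tree


def sample_outgroup(lt: LabeledHomologTree, subtree_tips: set[str],
                    seed: int, min_size: int = 20,
                    max_size: int = 50) -> list[str]:
    """Random outgroup sample from the clades sister to a subtree.

    Starts from the clade sister to the subtree's MRCA and moves to the
    next subtending clade while fewer than ``min_size`` candidates are
    available; samples uniformly without replacement, capped at
    ``max_size``.  Reaching the root with fewer than ``min_size``
    candidates returns everything available (with a warning).
    """
    import warnings

    tree = lt.tree
    idx = [i for i in tree.leaves if tree.names[i] in subtree_tips]
    if not idx:
        raise ValueError("subtree has no tips in the tree")
    node = idx[0]
    for i in idx[1:]:
        node = tree.mrca(node, i)
    candidates: list[str] = []
    j = node
    while j != tree.root and len(candidates) < min_size:
        parent = int(tree.parent[j])
        for sib in tree.children[parent]:
            if sib != j:
                candidates.extend(tree.names[i] for i in tree.leaf_set(sib)
                                  if tree.names[i] not in subtree_tips)
        j = parent
    if len(candidates) < min_size:
        warnings.warn("fewer than the minimum outgroup candidates available")
    rng = np.random.default_rng(seed)
    take = min(max_size, len(candidates))
    order = rng.permutation(len(candidates))[:take]
    return [candidates[i] for i in sorted(order)]


# ---------------------------------------------------------------------------
# Donor classification
# ---------------------------------------------------------------------------

def _rank_consensus(taxa: list[tuple[str, str, str]], level: float
                    ) -> tuple[str, str, float] | None:
    """Most specific rank whose modal label reaches the consensus level.

    Tips lacking a label at a rank are excluded from that rank's
    denominator.  Returns (rank, label, fraction) or None.
    """
    for ridx in (2, 1, 0):  # phylum, then superphylum, then domain
        labels = [t[ridx] for t in taxa if t[ridx]]
        if not labels:
            continue
        vals, counts = np.unique(labels, return_counts=True)
        top = int(np.argmax(counts))
        frac = counts[top] / len(labels)
        if frac >= level:
            return RANKS[ridx], str(vals[top]), float(frac)
    return None


def classify_donor(lt: LabeledHomologTree, family: str = "",
                   level: float = 0.75,
                   min_support: float = 0.80) -> DonorCall:
    """Donor lineage of the query clade in an ML subtree.

    The clade sister to the (monophyletic) query tips must have support
    >= ``min_support`` (0-1 scale); its taxonomy is pooled with the
    next subtending ("nested") clade and the most specific rank shared
    by >= ``level`` of the pooled, labeled tips is reported.  A tree
    without any non-query tips yields a de-novo candidate; all other
    failure modes yield "unresolved".
    """
    tree = lt.tree
    non_query = {tree.names[i] for i in tree.leaves} - lt.query
    if not non_query:
        return DonorCall(family, tree.root, "de-novo-candidate", level=level)
    if not lt.query:
        return DonorCall(family, -1, "unresolved", level=level)
    qidx = [i for i in tree.leaves if tree.names[i] in lt.query]
    node = qidx[0]
    for i in qidx[1:]:
        node = tree.mrca(node, i)
    clade_tips = {tree.names[i] for i in tree.leaf_set(node)}
    if clade_tips != lt.query:  # query tips not monophyletic
        return DonorCall(family, node, "unresolved", level=level)
    if node == tree.root:
        return DonorCall(family, node, "unresolved", level=level)
    parent = int(tree.parent[node])
    sisters = [c for c in tree.children[parent] if c != node]
    if len(sisters) != 1:
        return DonorCall(family, node, "unresolved", level=level)
    sister = sisters[0]
    sup = lt.support(sister) if not tree.is_leaf(sister) else 1.0
    if not np.isnan(sup) and sup < min_support:
        return DonorCall(family, node, "unresolved", level=level)
    pool = [tree.names[i] for i in tree.leaf_set(sister)]
    if parent != tree.root:
        gp = int(tree.parent[parent])
        for c in tree.children[gp]:
            if c != parent:
                pool.extend(tree.names[i] for i in tree.leaf_set(c))
    taxa = [lt.taxonomy.get(t, ("", "", "")) for t in pool
            if t not in lt.query]
    hit = _rank_consensus(taxa, level)
    if hit is None:
        return DonorCall(family, node, "unresolved", level=level)
    rank, label, frac = hit
    return DonorCall(family, node, "donor-assigned", label=label,
                     rank=rank, level=level, fraction=frac)
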