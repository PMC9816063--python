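"""Ancestral gene content and per-branch event inference.

Two complementary reconstructions are provided:

* :func:`wagner_parsimony` - gene-tree-unaware Wagner parsimony over
  per-genome copy numbers (asymmetric gain penalty, Sankoff-style
  dynamic programming over copy states).
* :func:`dtl_reconcile` / :func:`reconcile_sample` - gene-tree-aware
  parsimony reconciliation of each gene tree in a family's tree sample
  with the species tree under the undated
  duplication-transfer-loss model, aggregated into per-node event and
  copy *frequencies* (fraction of sampled reconciliations containing
  the event).

Downstream utilities implement the confident-event quantization
staircase (frequency >= 0.3 and < 1.3 counts as one event, >= 1.3 and
< 2.3 as two, ...), the copy-frequency presence rule, ancestral
proteome sizes from raw frequencies, and the subunit-majority rule for
protein-complex presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventTable, FamilyProfile
from .trees import Tree

__all__ = [
    "CopyProfile", "DtlCosts", "WagnerResult", "DtlResult",
    "wagner_parsimony", "dtl_reconcile", "reconcile_sample",
    "add_singletons", "quantize_events", "quantize_table",
    "ancestral_presence", "proteome_size", "complex_presence",
]

_INF = np.inf
_EPS = 1e-9


# ---------------------------------------------------------------------------
# Wagner parsimony on copy numbers
# ---------------------------------------------------------------------------

@dataclass
class CopyProfile:
    """Leaf copy numbers for one family, with the DP state ceiling M."""

    family: str
    copies: dict[str, int]
    max_state: int | None = None  # default: max(leaf copies) + 1

    def __post_init__(self) -> None:
        if not self.copies:
            raise ValueError("empty copy profile")
        if any(c < 0 or c != int(c) for c in self.copies.values()):
            raise ValueError("copy numbers must be non-negative integers")
        top = max(self.copies.values())
        if self.max_state is None:
            self.max_state = top + 1
        elif self.max_state < top:
            raise ValueError("max_state below observed copy number")


@dataclass
class WagnerResult:
    cost: float
    states: dict[str, int]          # node name -> inferred copy number
    gains: dict[str, int]           # per-branch copy increments
    losses: dict[str, int]          # per-branch copy decrements


def wagner_parsimony(tree: Tree, profile: CopyProfile,
                     gain_penalty: float = 1.0) -> WagnerResult:
    """Minimal-cost ancestral copy numbers under Wagner parsimony.

    Branch cost for a parent->child change ``d = child - parent`` is
    ``gain_penalty * max(0, d) + max(0, -d)`` (unit loss cost).  Ties
    are broken toward the smaller ancestral copy number.  Genomes
    absent from the profile count as zero copies; unknown genomes in
    the profile are an error.
    """
    leaf_names = set(tree.leaf_names)
    unknown = set(profile.copies) - leaf_names
    if unknown:
        raise ValueError(f"profile genomes not in tree: {sorted(unknown)}")
    m = profile.max_state
    states = np.arange(m + 1)
    # branch cost matrix: rows parent state, cols child state
    diff = states[None, :] - states[:, None]
    bcost = gain_penalty * np.maximum(0, diff) + np.maximum(0, -diff)

    n = tree.n_nodes
    cost = np.zeros((n, m + 1))
    for i in tree.postorder():
        if tree.is_leaf(i):
            obs = profile.copies.get(tree.names[i], 0)
            cost[i] = _INF
            cost[i][obs] = 0.0
        else:
            for c in tree.children[i]:
                cost[i] += (bcost + cost[c][None, :]).min(axis=1)
    root = tree.root
    assigned = np.zeros(n, dtype=int)
    assigned[root] = int(np.argmin(cost[root]))  # argmin -> smallest state
    total = float(cost[root][assigned[root]])
    for i in range(n - 2, -1, -1):  # preorder
        p = assigned[int(tree.parent[i])]
        assigned[i] = int(np.argmin(bcost[p] + cost[i]))
    out_states = {tree.names[i]: int(assigned[i]) for i in range(n)}
    gains, losses = {}, {}
    for i in range(n - 1):
        d = int(assigned[i]) - int(assigned[int(tree.parent[i])])
        gains[tree.names[i]] = max(0, d)
        losses[tree.names[i]] = max(0, -d)
    return WagnerResult(total, out_states, gains, losses)


# ---------------------------------------------------------------------------
# Undated DTL parsimony reconciliation
# ---------------------------------------------------------------------------

@dataclass
class DtlCosts:
    """Event costs for parsimony reconciliation (speciation costs 0)."""

    dup: float = 2.0
    transfer: float = 3.0
    loss: float = 1.0

    def __post_init__(self) -> None:
        if min(self.dup, self.transfer, self.loss) <= 0:
            raise ValueError("event costs must be > 0")


@dataclass
class DtlResult:
    """One optimal reconciliation, with events mapped to species nodes.

    Event count arrays are indexed by species postorder index; ``copies``
    counts the gene lineages crossing each species node.  Transfers are
    (donor branch, acceptor branch) species-index pairs; the per-node
    ``T`` count sits on the *acceptor* branch.
    """

    cost: float
    origination: int
    O: np.ndarray
    D: np.ndarray
    T: np.ndarray
    L: np.ndarray
    copies: np.ndarray
    transfers: list[tuple[int, int]] = field(default_factory=list)


class _DtlDP:
    """Dynamic program over (gene node, species node) pairs."""

    def __init__(self, stree: Tree, gtree: Tree, costs: DtlCosts,
                 leaf_map: dict[str, str]):
        for i in range(stree.n_nodes):
            if stree.children[i] and len(stree.children[i]) != 2:
                raise ValueError("DTL reconciliation requires a binary "
                                 "species tree")
        for i in range(gtree.n_nodes):
            if gtree.children[i] and len(gtree.children[i]) != 2:
                raise ValueError("gene tree must be binary (root unrooted "
                                 "inputs first)")
        self.s, self.g, self.k = stree, gtree, costs
        ns = stree.n_nodes
        self.sigma = {}
        sindex = stree.index
        for i in gtree.leaves:
            target = leaf_map.get(gtree.names[i], gtree.names[i])
            if target not in sindex or stree.children[sindex[target]]:
                raise ValueError(
                    f"gene leaf {gtree.names[i]!r} maps to no species leaf")
            self.sigma[i] = sindex[target]
        ng = gtree.n_nodes
        self.C = np.full((ng, ns), _INF)
        self.inS = np.full((ng, ns), _INF)
        self.in_child = np.full((ng, ns), -1, dtype=int)   # -1: stop here
        self.minsub = np.full((ng, ns), _INF)
        self.minsub_node = np.full((ng, ns), -1, dtype=int)
        self.out = np.full((ng, ns), _INF)
        self.out_node = np.full((ng, ns), -1, dtype=int)
        self._run()

    # -- forward pass ---------------------------------------------------
    def _run(self) -> None:
        s, g, k = self.s, self.g, self.k
        for u in g.postorder():
            if g.is_leaf(u):
                self.C[u][self.sigma[u]] = 0.0
            else:
                u1, u2 = g.children[u]
                in1, in2 = self.inS[u1], self.inS[u2]
                out1, out2 = self.out[u1], self.out[u2]
                dup = k.dup + in1 + in2
                tra = k.transfer + np.minimum(in1 + out2, in2 + out1)
                cu = np.minimum(dup, tra)
                for x in range(s.n_nodes):
                    if s.children[x]:
                        l, r = s.children[x]
                        spe = min(in1[l] + in2[r], in1[r] + in2[l])
                        if spe < cu[x]:
                            cu[x] = spe
                self.C[u] = cu
            self._fill_aux(u)

    def _fill_aux(self, u: int) -> None:
        s = self.s
        lam = self.k.loss
        cu = self.C[u]
        for x in s.postorder():
            # inS: best placement within subtree(x), one loss per edge
            best, arg = cu[x], -1
            msb, msn = cu[x], x
            for c in s.children[x]:
                v = lam + self.inS[u][c]
                if v < best - _EPS:
                    best, arg = v, c
                if self.minsub[u][c] < msb - _EPS:
                    msb, msn = self.minsub[u][c], int(self.minsub_node[u][c])
            self.inS[u][x], self.in_child[u][x] = best, arg
            self.minsub[u][x], self.minsub_node[u][x] = msb, msn
        for x in range(s.n_nodes - 1, -1, -1):  # preorder
            if x != s.root:
                p = int(s.parent[x])
                best, node = self.out[u][p], int(self.out_node[u][p])
                for sib in s.children[p]:
                    if sib == x:
                        continue
                    if self.minsub[u][sib] < best - _EPS:
                        best = self.minsub[u][sib]
                        node = int(self.minsub_node[u][sib])
                self.out[u][x], self.out_node[u][x] = best, node

    # -- traceback ------------------------------------------------------
    def extract(self) -> DtlResult:
        ns = self.s.n_nodes
        res = DtlResult(
            cost=0.0, origination=-1,
            O=np.zeros(ns, dtype=int), D=np.zeros(ns, dtype=int),
            T=np.zeros(ns, dtype=int), L=np.zeros(ns, dtype=int),
            copies=np.zeros(ns, dtype=int),
        )
        groot = self.g.root
        croot = self.C[groot]
        x0 = int(np.argmin(croot))
        if not np.isfinite(croot[x0]):
            raise ValueError("no finite reconciliation (unmapped leaves?)")
        res.cost = float(croot[x0])
        res.origination = x0
        res.O[x0] += 1
        self._resolve(groot, x0, res)
        return res

    def _descend(self, u: int, top: int, res: DtlResult) -> int:
        """Walk the optimal loss path of ``inS[u]`` from ``top`` down.

        Every fully crossed species node increments ``copies``; each
        skipped sibling records a loss.  Returns the landing node.
        """
        x = top
        while True:
            c = int(self.in_child[u][x])
            if c < 0:
                return x
            res.copies[x] += 1
            for sib in self.s.children[x]:
                if sib != c:
                    res.L[sib] += 1
            x = c

    def _resolve(self, u: int, x: int, res: DtlResult) -> None:
        """Emit the events of gene node ``u`` reconciled at species ``x``."""
        g, s, k = self.g, self.s, self.k
        if g.is_leaf(u):
            res.copies[x] += 1
            return
        u1, u2 = g.children[u]
        cux = self.C[u][x]
        # speciation first (tie order S < D < T), then duplication
        if s.children[x]:
            l, r = s.children[x]
            for a, b in ((l, r), (r, l)):
                if abs(self.inS[u1][a] + self.inS[u2][b] - cux) <= _EPS:
                    res.copies[x] += 1
                    self._resolve(u1, self._descend(u1, a, res), res)
                    self._resolve(u2, self._descend(u2, b, res), res)
                    return
        if abs(k.dup + self.inS[u1][x] + self.inS[u2][x] - cux) <= _EPS:
            res.D[x] += 1
            self._resolve(u1, self._descend(u1, x, res), res)
            self._resolve(u2, self._descend(u2, x, res), res)
            return
        for stay, move in ((u1, u2), (u2, u1)):
            if abs(k.transfer + self.inS[stay][x] + self.out[move][x] - cux) \
                    <= _EPS:
                z = int(self.out_node[move][x])
                res.T[z] += 1
                res.transfers.append((x, z))
                self._resolve(stay, self._descend(stay, x, res), res)
                self._resolve(move, self._descend(move, z, res), res)
                return
        raise AssertionError("traceback failed to re-derive the optimum")


def _enumerate_rootings(gtree: Tree) -> list[Tree]:
    """All rootings of an unrooted (basal-trifurcation) gene tree.

    Edges are taken in the deterministic postorder of the input; the
    edge index is therefore the tie-break order for rooting.
    """
    import dendropy

    rootings = []
    n_edges = gtree.n_nodes - 1
    for e in range(n_edges):
        dt = dendropy.Tree.get(data=gtree.to_newick(), schema="newick",
                               suppress_internal_node_taxa=True,
                               preserve_underscores=True)
        edges = [nd.edge for nd in dt.postorder_node_iter()
                 if nd.parent_node is not None]
        edge = edges[e]
        half = (edge.length or 0.0) / 2.0
        dt.reroot_at_edge(edge, length1=half, length2=half,
                          update_bipartitions=False)
        rootings.append(Tree.from_newick(dt.as_string(schema="newick",
                                                      suppress_rooting=True)))
    return rootings


def dtl_reconcile(stree: Tree, gtree: Tree, costs: DtlCosts | None = None,
                  leaf_map: dict[str, str] | None = None) -> DtlResult:
    """Minimum-cost undated DTL reconciliation of one gene tree.

    ``leaf_map`` sends gene-tree tip names to species-tree leaf names
    (identity by default).  Unrooted inputs (basal trifurcation) are
    rooted at the minimum-cost edge, ties broken by lowest edge index.
    Deterministic event tie-break: speciation < duplication < transfer,
    then lower species postorder index.
    """
    costs = costs or DtlCosts()
    leaf_map = leaf_map or {}
    if gtree.n_nodes == 1:
        # single-copy family: origination at the corresponding leaf
        target = leaf_map.get(gtree.names[0], gtree.names[0])
        ns = stree.n_nodes
        x = stree.index[target]
        res = DtlResult(0.0, x, np.zeros(ns, int), np.zeros(ns, int),
                        np.zeros(ns, int), np.zeros(ns, int),
                        np.zeros(ns, int))
        res.O[x] += 1
        res.copies[x] += 1
        return res
    if len(gtree.children[gtree.root]) > 2:
        best = None
        for rooted in _enumerate_rootings(gtree):
            cand = _DtlDP(stree, rooted, costs, leaf_map).extract()
            if best is None or cand.cost < best.cost - _EPS:
                best = cand
        return best
    return _DtlDP(stree, gtree, costs, leaf_map).extract()


# ---------------------------------------------------------------------------
# Frequency aggregation over gene-tree samples
# ---------------------------------------------------------------------------

def reconcile_sample(stree: Tree, profile: FamilyProfile,
                     costs: DtlCosts | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconcile every gene tree of a family and average the outcomes.

    Event frequencies at a node are occurrence counts across the K
    sampled reconciliations divided by K; the copy frequency is the
    mean lineage count.  Returns ``(event rows, transfer-route rows)``
    as data frames; event rows are restricted to species nodes touched
    by at least one reconciliation.
    """
    if not profile.gene_trees:
        raise ValueError(f"family {profile.family!r} has no gene trees")
    costs = costs or DtlCosts()
    leaf_map = profile.seq_to_genome()
    ns = stree.n_nodes
    acc = {key: np.zeros(ns) for key in "ODTLC"}
    routes: dict[tuple[int, int], int] = {}
    kk = len(profile.gene_trees)
    for gt in profile.gene_trees:
        res = dtl_reconcile(stree, gt, costs, leaf_map)
        for key, arr in (("O", res.O), ("D", res.D), ("T", res.T),
                         ("L", res.L), ("C", res.copies)):
            acc[key] += arr
        for d, a in res.transfers:
            routes[(d, a)] = routes.get((d, a), 0) + 1
    rows = []
    for x in range(ns):
        vals = {key: acc[key][x] / kk for key in "ODTLC"}
        if any(v > 0 for v in vals.values()):
            rows.append({"family": profile.family, "node": stree.names[x],
                         **vals})
    events = pd.DataFrame(rows, columns=["family", "node", "O", "D", "T",
                                         "L", "C"])
    route_rows = [{"family": profile.family, "donor": stree.names[d],
                   "acceptor": stree.names[a], "frequency": c / kk}
                  for (d, a), c in sorted(routes.items())]
    route_df = pd.DataFrame(route_rows, columns=["family", "donor",
                                                 "acceptor", "frequency"])
    return events, route_df


def add_singletons(table: EventTable, singletons: list[FamilyProfile],
                   stree: Tree) -> EventTable:
    """Append singleton families as originations at their leaf node.

    Each singleton contributes one origination (frequency 1) and copy
    frequency 1 at the species leaf of its only member.
    """
    rows = []
    leaf_names = set(stree.leaf_names)
    for prof in singletons:
        if len(prof.members) != 1:
            raise ValueError(f"{prof.family!r} is not a singleton")
        genome = prof.members[0][1]
        if genome not in leaf_names:
            raise ValueError(f"unknown genome {genome!r}")
        rows.append({"family": prof.family, "node": genome,
                     "O": 1.0, "D": 0.0, "T": 0.0, "L": 0.0, "C": 1.0})
    if not rows:
        return table
    frames = ([table.df, pd.DataFrame(rows)] if len(table.df)
              else [pd.DataFrame(rows)])
    df = pd.concat(frames, ignore_index=True)
    return EventTable(df, table.provenance)


# ---------------------------------------------------------------------------
# Quantization, presence, proteome size, complexes
# ---------------------------------------------------------------------------

def quantize_events(frequency: float, cutoff: float = 0.3) -> int:
    """Confident-event staircase: f < cutoff -> 0, else floor(f-cutoff)+1.

    Reproduces the reporting rule that a frequency >= 0.3 and < 1.3
    counts as one event, >= 1.3 and < 2.3 as two, and so on.  A small
    epsilon guards the staircase boundaries against float rounding.
    """
    if frequency < 0:
        raise ValueError("negative frequency")
    if frequency < cutoff:
        return 0
    return int(np.floor(frequency - cutoff + _EPS)) + 1


def quantize_table(table: EventTable, cutoff: float = 0.3) -> EventTable:
    if table.provenance != "raw":
        raise ValueError("can only quantize a raw table")
    df = table.df.copy()
    for col in ["O", "D", "T", "L", "C"]:
        df[col] = [quantize_events(v, cutoff) for v in df[col]]
    return EventTable(df, "quantized")


def ancestral_presence(table: EventTable, cutoff: float = 0.3
                       ) -> pd.DataFrame:
    """Presence calls: a family is present at a node iff C >= cutoff."""
    if table.provenance != "raw":
        raise ValueError("presence is defined on raw copy frequencies")
    df = table.df[["family", "node", "C"]].copy()
    df["present"] = df["C"] >= cutoff
    return df


def proteome_size(table: EventTable, node: str,
                  completeness: dict[str, float] | None = None) -> float:
    """Ancestral proteome size: sum of raw copy frequencies at a node.

    ``completeness`` optionally maps extant genomes to their estimated
    completeness fraction; copy frequencies at those leaves are scaled
    by 1/completeness to compensate for gene content missing from
    draft genomes.
    """
    if table.provenance != "raw":
        raise ValueError("proteome size uses raw copy frequencies")
    sub = table.df[table.df["node"] == node]
    if sub.empty and node not in set(table.df["node"]):
        raise KeyError(f"node {node!r} not present in event table")
    total = float(sub["C"].sum())
    if completeness and node in completeness:
        frac = completeness[node]
        if not 0 < frac <= 1:
            raise ValueError("completeness fraction must be in (0, 1]")
        total /= frac
    return total


def complex_presence(subunit_flags: list[bool],
                     fraction: float = 0.5) -> bool:
    """A complex is present iff >= ``fraction`` of its subunits are."""
    if not subunit_flags:
        raise ValueError("no subunits defined")
    return sum(bool(f) for f in subunit_flags) / len(subunit_flags) >= fraction
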