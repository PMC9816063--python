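"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* a birth-death species tree (branch lengths act as both time and
  expected substitutions/site, mean root-to-tip depth scaled to 1);
* gene families evolving along it by an origination / duplication /
  transfer / loss process (transfers land on branches that overlap the
  donor in depth-from-root, the undated stand-in for time), emitting
  leaf copy numbers, the induced gene trees and a complete event log;
* compositionally balanced alignments (Latin-square blocks over the
  amino-acid alphabet) with a planted taxon-specific compositional
  bias at known sites;
* per-route transfer processes with a planted highway at a fold-change;
* taxonomy-labeled homolog trees with a planted donor clade.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Alignment, EventTable, FamilyProfile
from .trees import Tree

__all__ = [
    "SimParams", "GroundTruth",
    "simulate_species_tree", "simulate_families",
    "simulate_biased_alignment", "plant_highway", "plant_donor_tree",
]


@dataclass
class SimParams:
    """Study conditions for the synthetic generators.

    Event rates are per gene lineage per unit branch length.  The root
    stem extends the origination lottery above the root so that a
    realistic share of families is ancestral to the whole clade.
    """

    n_genomes: int = 50
    birth: float = 1.0
    death: float = 0.2
    n_families: int = 200
    dup: float = 0.03
    transfer: float = 0.03
    loss: float = 0.06
    root_stem: float = 1.0
    highway_pair: tuple[str, str] | None = None
    highway_fold: float = 1.0
    aln_sites: int = 2000
    bias_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dup, self.transfer, self.loss, self.birth) < 0 \
                or self.death < 0:
            raise ValueError("rates must be >= 0")
        if self.highway_fold < 1:
            raise ValueError("highway fold-change must be >= 1")


@dataclass
class GroundTruth:
    """True events and states behind one synthetic dataset."""

    event_table: pd.DataFrame | None = None   # family,node,O,D,T,L (ints)
    copies: dict[str, np.ndarray] = field(default_factory=dict)
    transfers: list[tuple[str, str, str]] = field(default_factory=list)
    origination: dict[str, str] = field(default_factory=dict)
    extinct_families: list[str] = field(default_factory=list)
    planted_pair: tuple[str, str] | None = None
    planted_sites: np.ndarray | None = None
    biased_taxa: list[str] = field(default_factory=list)
    donor_phylum: str | None = None

    def routes(self) -> pd.DataFrame:
        """True transfer routes in the layout of reconciliation output."""
        rows = [{"family": f, "donor": d, "acceptor": a, "frequency": 1.0}
                for f, d, a in self.transfers]
        return pd.DataFrame(rows, columns=["family", "donor", "acceptor",
                                           "frequency"])

    def presence(self, tree: Tree) -> pd.DataFrame:
        """True presence flags per (node, family)."""
        rows = []
        for fam, arr in self.copies.items():
            for i in np.nonzero(arr)[0]:
                rows.append({"family": fam, "node": tree.names[i],
                             "C": float(arr[i]), "present": True})
        return pd.DataFrame(rows, columns=["family", "node", "C", "present"])


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

class _BDNode:
    __slots__ = ("t", "children", "dead", "name")

    def __init__(self, t: float):
        self.t = t
        self.children: list["_BDNode"] = []
        self.dead = False
        self.name = ""


def _lineage_count(birth: float, death: float, t_max: float,
                   rng: np.random.Generator) -> int:
    """Number of surviving lineages of a birth-death process at t_max,
    started from one lineage (used for calibration checks)."""
    k, t = 1, 0.0
    while k > 0:
        t += rng.exponential(1.0 / (k * (birth + death))) \
            if birth + death > 0 else np.inf
        if t > t_max:
            break
        if rng.random() < birth / (birth + death):
            k += 1
        else:
            k -= 1
    return k


def _grow(n: int, birth: float, death: float,
          rng: np.random.Generator) -> _BDNode | None:
    root = _BDNode(0.0)
    active = [root]
    t = 0.0
    while True:
        k = len(active)
        if k == 0:
            return None
        if k >= n:
            break
        t += rng.exponential(1.0 / (k * (birth + death)))
        i = rng.integers(k)
        node = active.pop(i)
        if rng.random() < birth / (birth + death):
            node.t = t
            node.children = [_BDNode(t), _BDNode(t)]
            active.extend(node.children)
        else:
            node.dead = True
    # truncate tips at a uniform point before the next scheduled event
    t_end = t + rng.random() * rng.exponential(1.0 / (n * (birth + death)))
    for node in active:
        node.t = t_end
    return root


def _prune_dead(node: _BDNode) -> _BDNode | None:
    if not node.children:
        return None if node.dead else node
    kids = [k for k in (_prune_dead(c) for c in node.children)
            if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    node.children = kids
    return node


def simulate_species_tree(n: int, birth: float = 1.0, death: float = 0.2,
                          seed: int = 0, max_retries: int = 100) -> Tree:
    """Birth-death species tree conditioned on ``n`` surviving leaves.

    Growth stops the moment the nth lineage appears; pendant branches
    are then extended to a uniform point before the next scheduled
    event.  Branch lengths are rescaled so the mean root-to-tip depth
    is 1.0.  Full extinction triggers a bounded resample.
    """
    if n < 3:
        raise ValueError("need n >= 3 leaves")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        root = _grow(n, birth, death, rng)
        if root is None:
            continue
        root = _prune_dead(root)
        if root is None or not root.children:
            continue
        leaves: list[_BDNode] = []

        def collect(nd: _BDNode) -> None:
            if not nd.children:
                leaves.append(nd)
            for c in nd.children:
                collect(c)

        collect(root)
        if len(leaves) < n:
            continue
        for i, leaf in enumerate(leaves):
            leaf.name = f"G{i:03d}"
        depth_sum = sum(leaf.t - root.t for leaf in leaves)
        scale = len(leaves) / depth_sum if depth_sum > 0 else 1.0

        def newick(nd: _BDNode, parent_t: float) -> str:
            length = (nd.t - parent_t) * scale
            if not nd.children:
                return f"{nd.name}:{length:.10g}"
            inner = ",".join(newick(c, nd.t) for c in nd.children)
            return f"({inner}):{length:.10g}"

        return Tree.from_newick(newick(root, root.t) + ";")
    raise RuntimeError("species-tree simulation kept going extinct")


# ---------------------------------------------------------------------------
# Gene-family evolution
# ---------------------------------------------------------------------------

class _GNode:
    __slots__ = ("t", "children", "tip")

    def __init__(self, t: float):
        self.t = t
        self.children: list["_GNode"] = []
        self.tip: str | None = None


def _prune_gene(node: _GNode) -> _GNode | None:
    if node.tip is not None:
        return node
    kids = [k for k in (_prune_gene(c) for c in node.children)
            if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    node.children = kids
    return node


def _gene_newick(node: _GNode, parent_t: float) -> str:
    length = max(node.t - parent_t, 0.0)
    if node.tip is not None:
        return f"{node.tip}:{length:.10g}"
    inner = ",".join(_gene_newick(c, node.t) for c in node.children)
    return f"({inner}):{length:.10g}"


class _FamilySim:
    """Origination/duplication/transfer/loss process on one species tree."""

    def __init__(self, tree: Tree, params: SimParams,
                 rng: np.random.Generator):
        self.tree = tree
        self.p = params
        self.rng = rng
        depths = tree.depths()
        n = tree.n_nodes
        self.bottom = depths
        self.top = np.empty(n)
        for i in range(n):
            par = int(tree.parent[i])
            self.top[i] = depths[par] if par != -1 else -params.root_stem
        self.blen = self.bottom - self.top
        self.tips: list[str] = []
        # per-lineage planted highway (optional; used by simulate_families)
        self.h_donor = self.h_acceptor = -1
        self.h_window = (0.0, 0.0)
        self.h_rate = 0.0
        if params.highway_pair is not None and params.highway_fold > 1:
            d, a = (tree.index[x] for x in params.highway_pair)
            if tree.comparable(d, a):
                raise ValueError("planted highway pair must be non-nested")
            w0 = max(self.top[d], self.top[a])
            w1 = min(self.bottom[d], self.bottom[a])
            if w1 <= w0:
                raise ValueError("planted highway pair does not overlap "
                                 "in depth")
            mid = 0.5 * (w0 + w1)
            k0 = max(1, len(self._alive(mid)) - 1)
            self.h_donor, self.h_acceptor = d, a
            self.h_window = (w0, w1)
            self.h_rate = params.transfer * (params.highway_fold - 1) / k0

    def _alive(self, t: float) -> list[int]:
        return [i for i in range(self.tree.n_nodes)
                if self.top[i] < t <= self.bottom[i]]

    def evolve(self, stack, D, T, L, copies, transfers, tips) -> None:
        """Run gene lineages down the species tree until they finish.

        ``stack`` holds (species branch, current time, gene node)
        entries; events are accumulated into the provided arrays.
        """
        tree, p, rng = self.tree, self.p, self.rng
        while stack:
            branch, t, gn = stack.pop()
            while True:
                extra = self.h_rate if branch == self.h_donor else 0.0
                total = p.dup + p.transfer + p.loss + extra
                te = t + (rng.exponential(1.0 / total) if total > 0
                          else np.inf)
                if te >= self.bottom[branch]:
                    # lineage crosses the species node at the branch end
                    copies[branch] += 1
                    gn.t = self.bottom[branch]
                    if tree.is_leaf(branch):
                        gn.tip = f"{tree.names[branch]}|{len(tips)}"
                        tips.append(gn.tip)
                    else:
                        for c in tree.children[branch]:
                            child = _GNode(gn.t)
                            gn.children.append(child)
                            stack.append((c, gn.t, child))
                    break
                u = rng.random() * total
                if u < p.dup:
                    D[branch] += 1
                    gn.t = te
                    left, right = _GNode(te), _GNode(te)
                    gn.children = [left, right]
                    stack.append((branch, te, right))
                    gn, t = left, te
                elif u < p.dup + p.transfer:
                    alive = [i for i in self._alive(te) if i != branch]
                    if alive:
                        rec = alive[int(rng.integers(len(alive)))]
                        T[rec] += 1
                        transfers.append((branch, rec))
                        gn.t = te
                        stay, moved = _GNode(te), _GNode(te)
                        gn.children = [stay, moved]
                        stack.append((rec, te, moved))
                        gn = stay
                    t = te
                elif u < p.dup + p.transfer + p.loss:
                    L[branch] += 1
                    break
                else:  # planted-highway extra transfer (thinned)
                    w0, w1 = self.h_window
                    if w0 < te <= w1:
                        rec = self.h_acceptor
                        T[rec] += 1
                        transfers.append((branch, rec))
                        gn.t = te
                        stay, moved = _GNode(te), _GNode(te)
                        gn.children = [stay, moved]
                        stack.append((rec, te, moved))
                        gn = stay
                    t = te

    def start_family(self, family: str):
        """Originate one family and evolve it; return the open state."""
        tree, rng = self.tree, self.rng
        n = tree.n_nodes
        O = np.zeros(n, int)
        D = np.zeros(n, int)
        T = np.zeros(n, int)
        L = np.zeros(n, int)
        copies = np.zeros(n, int)
        transfers: list[tuple[int, int]] = []
        # origination branch chosen proportionally to branch length
        weights = self.blen / self.blen.sum()
        b0 = int(rng.choice(n, p=weights))
        t0 = self.top[b0] + rng.random() * self.blen[b0]
        O[b0] += 1
        root = _GNode(t0)
        self.tips = []
        self.evolve([(b0, t0, root)], D, T, L, copies, transfers,
                    self.tips)
        return O, D, T, L, copies, transfers, root, t0, b0


def _emit_family(tree: Tree, family: str, O, D, T, L, copies, transfers,
                 root, b0: int, truth: GroundTruth, rows: list,
                 profiles: list[FamilyProfile]) -> None:
    """Fold one finished family into the truth tables and profiles."""
    truth.copies[family] = copies
    truth.origination[family] = tree.names[b0]
    truth.transfers.extend((family, tree.names[d], tree.names[a])
                           for d, a in transfers)
    for x in range(tree.n_nodes):
        if O[x] or D[x] or T[x] or L[x] or copies[x]:
            rows.append({"family": family, "node": tree.names[x],
                         "O": int(O[x]), "D": int(D[x]),
                         "T": int(T[x]), "L": int(L[x]),
                         "C": int(copies[x])})
    pruned = _prune_gene(root)
    if pruned is None:
        truth.extinct_families.append(family)
    elif pruned.tip is not None:  # single survivor
        genome = pruned.tip.split("|")[0]
        profiles.append(FamilyProfile(family, [(pruned.tip, genome)]))
    else:
        gt = Tree.from_newick(_gene_newick(pruned, pruned.t) + ";")
        members = [(name, name.split("|")[0]) for name in gt.leaf_names]
        profiles.append(FamilyProfile(family, members, [gt]))


def simulate_families(tree: Tree, params: SimParams
                      ) -> tuple[list[FamilyProfile], GroundTruth]:
    """Simulate gene families with a complete event log.

    Families originate on a branch chosen proportionally to branch
    length (a stem above the root included), then duplicate, transfer
    (to a uniformly chosen branch overlapping in depth) and die as a
    Poisson process along the species tree.  Returns family profiles
    (with induced gene trees for families of two or more surviving
    copies) and the ground truth: per-branch event counts, per-node
    lineage crossings, transfer donor/acceptor pairs and origination
    branches.  Fully extinct families appear only in
    ``GroundTruth.extinct_families``.
    """
    rng = np.random.default_rng(params.seed)
    sim = _FamilySim(tree, params, rng)
    profiles: list[FamilyProfile] = []
    truth = GroundTruth(planted_pair=params.highway_pair
                        if sim.h_donor >= 0 else None)
    rows = []
    for fid in range(params.n_families):
        family = f"F{fid:04d}"
        O, D, T, L, copies, transfers, root, t0, b0 = \
            sim.start_family(family)
        _emit_family(tree, family, O, D, T, L, copies, transfers, root,
                     b0, truth, rows, profiles)
    truth.event_table = pd.DataFrame(
        rows, columns=["family", "node", "O", "D", "T", "L", "C"])
    return profiles, truth


def _eligible_routes(tree: Tree, top: np.ndarray, bottom: np.ndarray
                     ) -> list[tuple[int, int, float, float]]:
    """Unordered non-nested branch pairs with a positive depth overlap."""
    routes = []
    n = tree.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            if tree.comparable(i, j):
                continue
            w0 = max(top[i], top[j])
            w1 = min(bottom[i], bottom[j])
            if w1 > w0:
                routes.append((i, j, w0, w1))
    return routes


def plant_highway(tree: Tree, params: SimParams
                  ) -> tuple[list[FamilyProfile], GroundTruth]:
    """Family simulation with route-uniform transfers and one highway.

    In this fixture ``params.transfer`` is the per-family probability
    of a transfer along each eligible route (unordered non-nested
    branch pair with overlapping depth ranges) - every route has the
    same base rate, which is the null hypothesis of the highway test.
    The planted route receives additional transfers with probability
    ``transfer * (fold - 1)``, i.e. a fold-change of its rate; with
    fold = 1 the planted pair is statistically indistinguishable from
    any other (the extra process draws nothing, so the output does not
    depend on which pair was designated).  Families otherwise evolve by
    the origination/duplication/loss process; a route transfer fires
    only when the family is present on the donor branch after its
    origination, and the transferred lineage then evolves on from the
    acceptor branch.
    """
    if params.highway_pair is None:
        raise ValueError("params.highway_pair is not set")
    d0, a0 = (tree.index[x] for x in params.highway_pair)
    if tree.comparable(d0, a0):
        raise ValueError("planted highway pair must be non-nested")
    rng = np.random.default_rng(params.seed)
    base = SimParams(**{**params.__dict__, "transfer": 0.0,
                        "highway_pair": None, "highway_fold": 1.0})
    sim = _FamilySim(tree, base, rng)
    routes = _eligible_routes(tree, sim.top, sim.bottom)
    if not any({i, j} == {d0, a0} for i, j, _, _ in routes):
        raise ValueError("planted highway pair does not overlap in depth")
    p_route = params.transfer
    p_extra = p_route * (params.highway_fold - 1.0)
    profiles: list[FamilyProfile] = []
    truth = GroundTruth(planted_pair=params.highway_pair)
    rows = []
    for fid in range(params.n_families):
        family = f"F{fid:04d}"
        O, D, T, L, copies, transfers, root, t0, b0 = \
            sim.start_family(family)
        tips = sim.tips

        def fire(donor: int, acceptor: int, w0: float, w1: float) -> None:
            tt = w0 + rng.random() * (w1 - w0)
            if copies[donor] == 0 or tt <= t0:
                return  # family absent from the donor branch
            T[acceptor] += 1
            transfers.append((donor, acceptor))
            moved = _GNode(tt)
            root.children.append(moved)
            sim.evolve([(acceptor, tt, moved)], D, T, L, copies,
                       transfers, tips)

        for i, j, w0, w1 in routes:
            if rng.random() < p_route:
                if rng.integers(2) == 0:
                    fire(i, j, w0, w1)
                else:
                    fire(j, i, w0, w1)
            if p_extra > 0 and {i, j} == {d0, a0}:
                if rng.random() < p_extra:
                    fire(d0, a0, w0, w1)
        _emit_family(tree, family, O, D, T, L, copies, transfers, root,
                     b0, truth, rows, profiles)
    truth.event_table = pd.DataFrame(
        rows, columns=["family", "node", "O", "D", "T", "L", "C"])
    return profiles, truth


def _latin_square(rng: np.random.Generator) -> np.ndarray:
    """Randomised 20x20 Latin square over the residue codes 0..19."""
    base = (np.arange(20)[:, None] + np.arange(20)[None, :]) % 20
    rows = rng.permutation(20)
    cols = rng.permutation(20)
    symbols = rng.permutation(20)
    return symbols[base[np.ix_(rows, cols)]]


def simulate_biased_alignment(taxa: list[str], n_sites: int,
                              bias_fraction: float,
                              biased_taxa: list[str], seed: int = 0,
                              bias_boost: float = 6.0
                              ) -> tuple[Alignment, GroundTruth]:
    """Alignment with a planted taxon-specific compositional bias.

    The unbiased background is compositionally *balanced* by
    construction: sites are generated in blocks of 20 columns, each
    block a randomised Latin square over the amino-acid alphabet, so
    every taxon row and (with >= 20 taxa) every column carries each
    residue equally often.  All taxa therefore match the global
    composition exactly and the chi-square composition test has
    nothing to reject.  At a planted fraction of sites the biased taxa
    redraw their residue from a shifted distribution (the first five
    residues of the alphabet boosted ``bias_boost``-fold), making
    those taxa - and only those sites - compositionally heterogeneous.
    Planted column indices are recorded in the ground truth.
    """
    from .io import AMINO_ACIDS

    if not 0 <= bias_fraction < 1:
        raise ValueError("bias_fraction must be in [0, 1)")
    unknown = set(biased_taxa) - set(taxa)
    if unknown:
        raise ValueError(f"biased taxa not in taxa set: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    n_taxa = len(taxa)
    blocks = []
    for _ in range(-(-n_sites // 20)):
        stack = [_latin_square(rng) for _ in range(-(-n_taxa // 20))]
        blocks.append(np.vstack(stack)[:n_taxa])
    codes = np.hstack(blocks)[:, :n_sites]
    n_planted = int(round(bias_fraction * n_sites))
    planted = np.sort(rng.choice(n_sites, size=n_planted, replace=False))
    if n_planted:
        shifted = np.ones(20)
        shifted[:5] *= bias_boost
        shifted /= shifted.sum()
        for t in biased_taxa:
            r = taxa.index(t)
            codes[r, planted] = rng.choice(20, size=n_planted, p=shifted)
    aln = Alignment(list(taxa), aas[codes])
    truth = GroundTruth(planted_sites=planted,
                        biased_taxa=list(biased_taxa))
    return aln, truth


# ---------------------------------------------------------------------------
# Planted donor trees
# ---------------------------------------------------------------------------

#: phylum -> (domain, superphylum) for label sampling
_LINEAGES = {
    "Proteobacteria": ("Bacteria", "Gracilicutes"),
    "Bacteroidetes": ("Bacteria", "Gracilicutes"),
    "Firmicutes": ("Bacteria", "Terrabacteria"),
    "Actinobacteria": ("Bacteria", "Terrabacteria"),
    "Cyanobacteria": ("Bacteria", "Terrabacteria"),
    "Euryarchaeota": ("Archaea", "Euryarchaeota"),
    "Crenarchaeota": ("Archaea", "TACK"),
    "Asgardarchaeota": ("Archaea", "Asgard"),
}
_QUERY_LINEAGE = ("Bacteria", "PVC", "Chlamydiae")


def plant_donor_tree(query_size: int = 5,
                     donor_phylum: str = "Proteobacteria",
                     purity: float = 1.0, seed: int = 0,
                     n_sister: int = 10, n_nested: int = 10,
                     n_distractor_clades: int = 3,
                     distractor_size: int = 6):
    """Homolog tree with the query clade nested in a donor clade.

    The query clade's sister and the subtending ("nested") clade carry
    the donor phylum's taxonomy on an exact ``purity`` fraction of
    their pooled tips; contaminant tips get lineages from a different
    domain, so no rank reaches a consensus above ``purity``.  All
    supports are 95.  Distractor clades with mixed labels surround the
    planted structure.
    """
    from .hgt_donor import LabeledHomologTree

    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must be in (0.5, 1]")
    if donor_phylum not in _LINEAGES:
        raise ValueError(f"unknown donor phylum {donor_phylum!r}")
    rng = np.random.default_rng(seed)
    donor_dom, donor_sup = _LINEAGES[donor_phylum]
    foreign = [p for p, (dom, _) in _LINEAGES.items() if dom != donor_dom]

    counter = [0]

    def tip(dom: str, sup: str, phy: str, query: bool = False) -> str:
        counter[0] += 1
        bl = 0.05 + 0.25 * rng.random()
        flag = "1" if query else "0"
        return f"t{counter[0]:03d}|{dom}|{sup}|{phy}|{flag}:{bl:.4f}"

    def clade(tips: list[str]) -> str:
        inner = tips[0]
        for t in tips[1:]:
            bl = 0.05 + 0.25 * rng.random()
            inner = f"({inner},{t})95:{bl:.4f}"
        return inner

    # exact donor-label count over the pooled sister+nested tips
    n_pool = n_sister + n_nested
    n_donor = int(round(purity * n_pool))
    donor_flags = np.zeros(n_pool, dtype=bool)
    donor_flags[rng.choice(n_pool, size=n_donor, replace=False)] = True
    pool_tips = []
    for flag in donor_flags:
        if flag:
            pool_tips.append(tip(donor_dom, donor_sup, donor_phylum))
        else:
            phy = foreign[int(rng.integers(len(foreign)))]
            dom, sup = _LINEAGES[phy]
            pool_tips.append(tip(dom, sup, phy))
    sister_tips, nested_tips = pool_tips[:n_sister], pool_tips[n_sister:]
    query_tips = [tip(*_QUERY_LINEAGE, query=True)
                  for _ in range(query_size)]

    core = (f"(({clade(query_tips)},{clade(sister_tips)})95:0.1,"
            f"{clade(nested_tips)})95:0.1")
    phyla = list(_LINEAGES)
    distractors = []
    for _ in range(n_distractor_clades):
        dt = []
        for _ in range(distractor_size):
            phy = phyla[int(rng.integers(len(phyla)))]
            dom, sup = _LINEAGES[phy]
            dt.append(tip(dom, sup, phy))
        distractors.append(clade(dt))
    newick = core
    for d in distractors:
        newick = f"({newick},{d})95:0.1"
    lt = LabeledHomologTree.from_newick(f"({newick});")
    truth = GroundTruth(donor_phylum=donor_phylum)
    return lt, truth
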