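"""Validation experiments run under the package's study conditions.

Each function sets up synthetic data with known ground truth (or an
exhaustive oracle), runs the corresponding pipeline stage, and returns
summary operating characteristics.  The brute-force reconciliation
oracles enumerate every ancestral assignment / reconciliation
explicitly and share no code with the dynamic programs they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .comp_trim import chi2_trim, composition_tests
from .io import EventTable
from .reconcile import (CopyProfile, DtlCosts, add_singletons, dtl_reconcile,
                        proteome_size, quantize_table, reconcile_sample,
                        wagner_parsimony)
from .simulate import (SimParams, plant_donor_tree, plant_highway,
                       simulate_biased_alignment, simulate_families,
                       simulate_species_tree)
from .transfer_stats import build_network, highway_test
from .trees import Tree

__all__ = [
    "wagner_brute_force", "dtl_brute_force",
    "wagner_oracle_experiment", "dtl_oracle_experiment",
    "event_recovery_experiment", "trim_experiment",
    "highway_experiment", "donor_experiment", "binomial_exact_experiment",
    "pick_planted_pair",
]


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def wagner_brute_force(tree: Tree, profile: CopyProfile,
                       gain_penalty: float = 1.0) -> float:
    """Minimum Wagner cost by exhaustive enumeration of ancestral states."""
    m = profile.max_state
    internals = [i for i in tree.postorder() if not tree.is_leaf(i)]
    leaf_state = {i: profile.copies.get(tree.names[i], 0)
                  for i in tree.leaves}
    best = math.inf
    for combo in itertools.product(range(m + 1), repeat=len(internals)):
        state = dict(zip(internals, combo)) | leaf_state
        cost = 0.0
        for i in range(tree.n_nodes - 1):
            d = state[i] - state[int(tree.parent[i])]
            cost += gain_penalty * max(0, d) + max(0, -d)
        best = min(best, cost)
    return best


def dtl_brute_force(stree: Tree, gtree: Tree, costs: DtlCosts,
                    leaf_map: dict[str, str]) -> float:
    """Minimum DTL cost by exhaustive enumeration of node mappings.

    Every assignment of gene-tree internal nodes to species nodes is
    scored by choosing, per gene node, the cheapest consistent event
    (speciation, duplication or transfer) with losses charged per edge
    descended; inconsistent assignments are discarded.
    """
    ns = stree.n_nodes
    depth = np.zeros(ns, dtype=int)
    for i in range(ns - 2, -1, -1):
        depth[i] = depth[int(stree.parent[i])] + 1

    def under_eq(y: int, x: int) -> bool:
        return y == x or stree.is_ancestor(x, y)

    def edist(x: int, y: int) -> int:
        return int(depth[y] - depth[x])

    sigma = {u: stree.index[leaf_map.get(gtree.names[u], gtree.names[u])]
             for u in gtree.leaves}
    internals = [u for u in gtree.postorder() if not gtree.is_leaf(u)]
    dd, tt, ll = costs.dup, costs.transfer, costs.loss
    best = math.inf
    for combo in itertools.product(range(ns), repeat=len(internals)):
        mapping = dict(zip(internals, combo)) | sigma
        total = 0.0
        for u in internals:
            x = mapping[u]
            u1, u2 = gtree.children[u]
            y1, y2 = mapping[u1], mapping[u2]
            options = []
            if stree.children[x]:
                l, r = stree.children[x]
                for a, b in ((l, r), (r, l)):
                    if under_eq(y1, a) and under_eq(y2, b):
                        options.append(ll * (edist(a, y1) + edist(b, y2)))
            if under_eq(y1, x) and under_eq(y2, x):
                options.append(dd + ll * (edist(x, y1) + edist(x, y2)))
            for stay, move in ((y1, y2), (y2, y1)):
                if under_eq(stay, x) and not stree.comparable(move, x):
                    options.append(tt + ll * edist(x, stay))
            if not options:
                total = math.inf
                break
            total += min(options)
        best = min(best, total)
    return best


# ---------------------------------------------------------------------------
# Random instances
# ---------------------------------------------------------------------------

def _random_copy_instance(rng: np.random.Generator
                          ) -> tuple[Tree, CopyProfile]:
    n = int(rng.integers(3, 7))
    tree = simulate_species_tree(n, seed=int(rng.integers(2 ** 31)))
    copies = {name: int(rng.integers(0, 4)) for name in tree.leaf_names}
    if sum(copies.values()) == 0:
        copies[tree.leaf_names[0]] = 1
    return tree, CopyProfile("fam", copies)


def _random_gene_tree(rng: np.random.Generator, species_leaves: list[str]
                      ) -> tuple[Tree, dict[str, str]]:
    k = int(rng.integers(2, 5))
    names = [f"g{i}" for i in range(k)]
    leaf_map = {g: species_leaves[int(rng.integers(len(species_leaves)))]
                for g in names}
    # random binary topology by sequential attachment
    subtrees = [f"{g}:1" for g in names]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(int(j))
        a = subtrees.pop(int(i))
        subtrees.append(f"({a},{b}):1")
    return Tree.from_newick(subtrees[0] + ";"), leaf_map


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def wagner_oracle_experiment(n_instances: int = 100, seed: int = 0
                             ) -> dict:
    """DP-vs-enumeration agreement for Wagner parsimony costs."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        tree, profile = _random_copy_instance(rng)
        dp = wagner_parsimony(tree, profile).cost
        bf = wagner_brute_force(tree, profile)
        agree += int(abs(dp - bf) < 1e-9)
    return {"agreement": agree, "n": n_instances}


def dtl_oracle_experiment(n_instances: int = 100, seed: int = 0) -> dict:
    """DP-vs-enumeration agreement plus cost monotonicity for DTL."""
    rng = np.random.default_rng(seed)
    agree = mono_ok = 0
    transfer_free = True
    base = DtlCosts(2.0, 3.0, 1.0)
    for _ in range(n_instances):
        n = int(rng.integers(3, 5))
        stree = simulate_species_tree(n, seed=int(rng.integers(2 ** 31)))
        gtree, leaf_map = _random_gene_tree(rng, stree.leaf_names)
        dp = dtl_reconcile(stree, gtree, base, leaf_map).cost
        bf = dtl_brute_force(stree, gtree, base, leaf_map)
        agree += int(abs(dp - bf) < 1e-9)
        costs_up = [DtlCosts(4.0, 3.0, 1.0), DtlCosts(2.0, 6.0, 1.0),
                    DtlCosts(2.0, 3.0, 2.0)]
        mono_ok += int(all(
            dtl_reconcile(stree, gtree, c, leaf_map).cost >= dp - 1e-9
            for c in costs_up))
        no_t = dtl_reconcile(stree, gtree, DtlCosts(2.0, 1e9, 1.0),
                             leaf_map)
        transfer_free &= int(no_t.T.sum()) == 0
    return {"agreement": agree, "monotone": mono_ok,
            "transfer_free_at_infinite_cost": bool(transfer_free),
            "n": n_instances}


def event_recovery_experiment(n_datasets: int = 10, seed: int = 0,
                              n_genomes: int = 50, n_families: int = 200
                              ) -> dict:
    """Reconcile simulated families and compare with the event log.

    A branch counts as recovered when each of the quantized O/D/T/L
    sums over families is within +-1 of the simulated truth.  Root
    proteome sizes (sum of raw copy frequencies) are compared with the
    true number of families crossing the root.
    """
    rng = np.random.default_rng(seed)
    branch_fracs, proteome_errs = [], []
    for _ in range(n_datasets):
        s = int(rng.integers(2 ** 31))
        tree = simulate_species_tree(n_genomes, seed=s)
        params = SimParams(n_genomes=n_genomes, n_families=n_families,
                           seed=s)
        profiles, truth = simulate_families(tree, params)
        frames, singles = [], []
        for prof in profiles:
            if prof.is_singleton:
                singles.append(prof)
            else:
                ev, _ = reconcile_sample(tree, prof)
                frames.append(ev)
        table = add_singletons(
            EventTable(pd.concat(frames, ignore_index=True)), singles, tree)
        quant = quantize_table(table)
        inferred = quant.df.groupby("node")[["O", "D", "T", "L"]].sum()
        target = truth.event_table.groupby("node")[["O", "D", "T", "L"]].sum()
        ok = 0
        for name in tree.names:
            iv = inferred.loc[name] if name in inferred.index else None
            tv = target.loc[name] if name in target.index else None
            diffs = [abs((0 if iv is None else iv[k])
                         - (0 if tv is None else tv[k]))
                     for k in "ODTL"]
            ok += int(max(diffs) <= 1)
        branch_fracs.append(ok / tree.n_nodes)
        root = tree.names[tree.root]
        inferred_root = proteome_size(table, root)
        true_root = sum(1 for arr in truth.copies.values()
                        if arr[tree.root] > 0)
        proteome_errs.append(abs(inferred_root - true_root)
                             / max(true_root, 1))
    return {"branch_recovery": branch_fracs,
            "proteome_rel_error": proteome_errs, "n": n_datasets}


def trim_experiment(n_null: int = 100, n_planted: int = 10, seed: int = 0,
                    n_taxa: int = 20, n_sites: int = 2000,
                    bias_fraction: float = 0.3, alpha: float = 0.05) -> dict:
    """Type-I and power characteristics of chi-square trimming."""
    rng = np.random.default_rng(seed)
    taxa = [f"T{i:02d}" for i in range(n_taxa)]
    triggered = 0
    for _ in range(n_null):
        aln, _ = simulate_biased_alignment(
            taxa, n_sites, 0.0, [], seed=int(rng.integers(2 ** 31)))
        triggered += int(any(r.p_value <= alpha
                             for r in composition_tests(aln)))
    enrichments, cleared, converged = [], 0, 0
    for _ in range(n_planted):
        aln, truth = simulate_biased_alignment(
            taxa, n_sites, bias_fraction, [taxa[0]],
            seed=int(rng.integers(2 ** 31)))
        res = chi2_trim(aln, alpha=alpha)
        removed = set(res.removed_sites.tolist())
        planted = set(truth.planted_sites.tolist())
        if removed:
            enrichments.append((len(removed & planted) / len(removed))
                               / (len(planted) / n_sites))
        post = composition_tests(res.alignment)
        cleared += int(post[0].p_value > alpha)
        converged += int(not res.exhausted
                         and all(r.p_value > alpha for r in post))
    return {"null_trigger": triggered, "n_null": n_null,
            "enrichment": enrichments, "cleared": cleared,
            "converged": converged, "n_planted": n_planted}


def pick_planted_pair(tree: Tree) -> tuple[str, str]:
    """Deterministic highway pair: the non-nested branch pair with the
    largest depth overlap (the easiest biologically valid route)."""
    depths = tree.depths()
    top = [depths[int(tree.parent[i])] if tree.parent[i] != -1 else -1.0
           for i in range(tree.n_nodes)]
    best = None
    for a in range(tree.n_nodes):
        for b in range(a + 1, tree.n_nodes):
            if tree.comparable(a, b):
                continue
            w = min(depths[a], depths[b]) - max(top[a], top[b])
            if w > 0 and (best is None or w > best[0]):
                best = (w, a, b)
    if best is None:
        raise ValueError("tree has no eligible branch pair")
    return tree.names[best[1]], tree.names[best[2]]


def highway_experiment(n_seeds: int = 20, seed: int = 0,
                       n_genomes: int = 12, n_families: int = 250,
                       route_probability: float = 0.04,
                       fold: float = 10.0) -> dict:
    """Detection power and null false-flag rate of highway testing.

    Each replicate simulates an all-ancestral family set with
    route-uniform transfers; the planted run multiplies one route by
    ``fold`` and the matched null run uses fold = 1.
    """
    rng = np.random.default_rng(seed)
    detected = null_flagged = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2 ** 31))
        tree = simulate_species_tree(n_genomes, seed=s)
        pair = pick_planted_pair(tree)
        common = dict(n_genomes=n_genomes, n_families=n_families,
                      transfer=route_probability, dup=0.0, loss=0.0,
                      root_stem=1000.0, highway_pair=pair, seed=s)
        _, truth = plant_highway(tree, SimParams(highway_fold=fold,
                                                 **common))
        net = build_network(truth.routes(), truth.presence(tree), tree)
        sig = net[net["significant"]]
        hit = (((sig["a"] == pair[0]) & (sig["b"] == pair[1]))
               | ((sig["a"] == pair[1]) & (sig["b"] == pair[0]))).any()
        detected += int(hit)
        _, truth0 = plant_highway(tree, SimParams(highway_fold=1.0,
                                                  **common))
        net0 = build_network(truth0.routes(), truth0.presence(tree), tree)
        null_flagged += int(net0["significant"].any())
    return {"detected": detected, "null_flagged": null_flagged,
            "n": n_seeds}


def donor_experiment(n_fixtures: int = 50, seed: int = 0,
                     purity: float = 0.8) -> dict:
    """Planted-donor recovery of the homolog-tree classification rules."""
    from .hgt_donor import classify_donor

    rng = np.random.default_rng(seed)
    recovered = strict_unresolved = 0
    for _ in range(n_fixtures):
        s = int(rng.integers(2 ** 31))
        lt, truth = plant_donor_tree(query_size=5, purity=purity, seed=s)
        call = classify_donor(lt, "fam", level=0.75)
        recovered += int(call.status == "donor-assigned"
                         and call.label == truth.donor_phylum)
        strict = classify_donor(lt, "fam", level=0.90)
        strict_unresolved += int(strict.status == "unresolved")
    return {"recovered": recovered, "strict_unresolved": strict_unresolved,
            "n": n_fixtures}


def binomial_exact_experiment(max_n: int = 12) -> dict:
    """Agreement of the binomial tail with explicit outcome enumeration."""
    worst = 0.0
    checked = 0
    for n in range(1, max_n + 1):
        for p0 in (0.1, 0.3, 0.5):
            for x in range(n + 1):
                total = 0.0
                for bits in itertools.product((0, 1), repeat=n):
                    k = sum(bits)
                    if k >= x:
                        total += p0 ** k * (1 - p0) ** (n - k)
                worst = max(worst, abs(highway_test(x, n, p0) - total))
                checked += 1
    return {"max_abs_error": worst, "n": checked}
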