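"""Transfer rates, group comparisons and transfer-highway detection.

The per-branch transfer rate is the summed (raw) transfer frequency on
a branch divided by the branch length in expected substitutions per
site.  Over-represented donor-acceptor routes ("gene transfer
highways") are found by a one-sided binomial test of the transferred
family count against a null probability equal to the *median
transferred fraction* across pairs, with Benjamini-Hochberg control of
the false discovery rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import EventTable
from .trees import Tree

__all__ = [
    "BranchRate", "branch_transfer_rate", "compare_rates",
    "highway_null", "highway_test", "bh_fdr",
    "build_network", "network_to_graph",
]


@dataclass
class BranchRate:
    branch: str       # species node subtending the branch
    transfers: float  # summed transfer frequency on the branch
    length: float     # substitutions/site
    rate: float       # transfers / length


def branch_transfer_rate(table: EventTable, tree: Tree) -> list[BranchRate]:
    """Per-branch transfer rate; zero-length branches are excluded
    (with a warning) since the rate is undefined there."""
    table.validate_nodes(tree)
    sums = table.df.groupby("node")["T"].sum()
    out = []
    for i in range(tree.n_nodes - 1):  # every non-root node = one branch
        name = tree.names[i]
        t = float(sums.get(name, 0.0))
        ell = float(tree.lengths[i])
        if ell <= 0:
            warnings.warn(f"branch {name!r} has zero length; excluded "
                          "from rate computation")
            continue
        out.append(BranchRate(name, t, ell, t / ell))
    return out


def compare_rates(group_a, group_b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value comparing two sets of branch rates.

    Exact null distribution for combined n <= 20 without ties; normal
    approximation with tie correction otherwise.  ``alternative``
    refers to group A relative to group B.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def highway_null(pairs: pd.DataFrame) -> float:
    """Null transfer probability: median of x/n over eligible pairs.

    ``pairs`` needs columns ``x`` (transferred families) and ``n``
    (shared families); pairs with n = 0 are excluded.
    """
    elig = pairs[pairs["n"] > 0]
    if elig.empty:
        raise ValueError("no pairs with shared families")
    return float(np.median(elig["x"] / elig["n"]))


def highway_test(x: int, n: int, p0: float) -> float:
    """One-sided binomial tail P(X >= x), X ~ Binomial(n, p0).

    Exact summation over the upper tail (no normal approximation).
    """
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if x == 0:
        return 1.0
    p = 0.0
    for k in range(x, n + 1):
        p += math.comb(n, k) * p0 ** k * (1.0 - p0) ** (n - k)
    return min(1.0, p)


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def _eligible_pairs(tree: Tree, nodes: list[str] | None) -> list[tuple[str, str]]:
    """Unordered node pairs that could in principle exchange genes.

    Eligible pairs are non-nested (neither node ancestral to the other)
    and overlap in depth from the root - the undated proxy for lineages
    that coexisted.  Nested pairs share families trivially and nodes
    from disjoint eras cannot transfer, so both would only dilute the
    binomial null.
    """
    names = nodes if nodes is not None else list(tree.names)
    idx = [tree.index[n] for n in names]
    bottom = tree.depths()
    top = np.array([bottom[int(tree.parent[i])] if tree.parent[i] != -1
                    else -np.inf for i in range(tree.n_nodes)])
    pairs = []
    for i, a in enumerate(idx):
        for b in idx[i + 1:]:
            if tree.comparable(a, b):
                continue
            if min(bottom[a], bottom[b]) > max(top[a], top[b]):
                pairs.append((tree.names[a], tree.names[b]))
    return pairs


def build_network(routes: pd.DataFrame, presence: pd.DataFrame, tree: Tree,
                  alpha: float = 0.05, cutoff: float = 0.3,
                  nodes: list[str] | None = None) -> pd.DataFrame:
    """Highway statistics for every unordered non-nested node pair.

    ``routes`` carries per-family transfer annotations (columns family,
    donor, acceptor, frequency); ``presence`` is the output of
    :func:`ace.reconcile.ancestral_presence`.  For a pair, ``n`` is the
    number of families present at both nodes and ``x`` the number of
    those families with a confident transfer (frequency >= cutoff)
    between them in either direction.  The binomial null probability is
    the median x/n over all pairs; q-values are Benjamini-Hochberg.
    Directed route counts are retained in ``x_ab``/``x_ba``.
    """
    if not {"donor", "acceptor", "family"} <= set(routes.columns):
        raise ValueError("routes require donor/acceptor/family columns")
    pres = presence[presence["present"]]
    by_node: dict[str, set[str]] = {
        n: set(sub["family"]) for n, sub in pres.groupby("node")}
    conf = routes[routes["frequency"] >= cutoff]
    directed: dict[tuple[str, str], set[str]] = {}
    for row in conf.itertuples(index=False):
        directed.setdefault((row.donor, row.acceptor), set()).add(row.family)
    rows = []
    for a, b in _eligible_pairs(tree, nodes):
        shared = by_node.get(a, set()) & by_node.get(b, set())
        ab = directed.get((a, b), set()) & shared
        ba = directed.get((b, a), set()) & shared
        rows.append({"a": a, "b": b, "n": len(shared),
                     "x": len(ab | ba), "x_ab": len(ab), "x_ba": len(ba)})
    net = pd.DataFrame(rows, columns=["a", "b", "n", "x", "x_ab", "x_ba"])
    if net.empty or (net["n"] > 0).sum() == 0:
        net["p0"] = np.nan
        net["p"] = np.nan
        net["q"] = np.nan
        net["significant"] = False
        return net
    p0 = highway_null(net)
    net["p0"] = p0
    net["p"] = [highway_test(int(r.x), int(r.n), p0) if r.n > 0 else 1.0
                for r in net.itertuples(index=False)]
    q, flags = bh_fdr(net["p"], alpha)
    net["q"] = q
    net["significant"] = flags
    return net


def network_to_graph(net: pd.DataFrame,
                     significant_only: bool = True) -> nx.DiGraph:
    """Directed transfer graph for export (edge-list TSV / GraphML)."""
    g = nx.DiGraph()
    sub = net[net["significant"]] if significant_only else net
    for r in sub.itertuples(index=False):
        if r.x_ab > 0 or not significant_only:
            g.add_edge(r.a, r.b, transfers=int(r.x_ab), shared=int(r.n),
                       q=float(r.q) if np.isfinite(r.q) else 1.0)
        if r.x_ba > 0:
            g.add_edge(r.b, r.a, transfers=int(r.x_ba), shared=int(r.n),
                       q=float(r.q) if np.isfinite(r.q) else 1.0)
    return g
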