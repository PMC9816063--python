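"""Chi-square trimming of compositionally heterogeneous alignment sites.

Each taxon's amino-acid composition is compared with the global (pooled)
composition of the alignment by a chi-square goodness-of-fit test with
19 degrees of freedom; gaps and ambiguity codes are excluded from both
observed and expected counts.  While any taxon is significantly
heterogeneous (P <= alpha), the most heterogeneous sites - ranked by a
site-level chi-square score against the global composition - are removed
in increments of 1% of the *original* alignment length, and the tests
are recomputed on the reduced alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Alignment

__all__ = ["CompositionTestResult", "taxon_chi2", "composition_tests",
           "site_scores", "chi2_trim", "TrimResult"]

_DF = 19  # 20 residue classes - 1


@dataclass
class CompositionTestResult:
    taxon: str
    statistic: float
    dof: int
    p_value: float


def _counts(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """(per-taxon 20-counts, global frequency vector) of an alignment."""
    codes = aln.residue_codes()
    n_taxa = aln.n_taxa
    per_taxon = np.zeros((n_taxa, 20))
    for t in range(n_taxa):
        row = codes[t]
        per_taxon[t] = np.bincount(row[row >= 0], minlength=20)
    total = per_taxon.sum()
    if total == 0:
        raise ValueError("alignment has no unambiguous residues")
    return per_taxon, per_taxon.sum(axis=0) / total


def composition_tests(aln: Alignment) -> list[CompositionTestResult]:
    """Per-taxon chi-square composition tests against the pooled frequencies."""
    per_taxon, freq = _counts(aln)
    out = []
    for t, taxon in enumerate(aln.ids):
        obs = per_taxon[t]
        n = obs.sum()
        if n == 0:
            raise ValueError(f"taxon {taxon!r} has no unambiguous residues")
        exp = n * freq
        mask = exp > 0
        stat = float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))
        p = float(stats.chi2.sf(stat, _DF))
        out.append(CompositionTestResult(taxon, stat, _DF, p))
    return out


def taxon_chi2(aln: Alignment, taxon: str) -> CompositionTestResult:
    if taxon not in aln.ids:
        raise KeyError(taxon)
    return composition_tests(aln)[aln.ids.index(taxon)]


def site_scores(aln: Alignment) -> np.ndarray:
    """Per-site compositional heterogeneity score.

    Site chi-square of the column's residue counts against the global
    composition; all-gap columns score 0 by convention.  Higher scores
    mark more heterogeneous sites.
    """
    codes = aln.residue_codes()
    _, freq = _counts(aln)
    n_sites = aln.n_sites
    col_counts = np.zeros((20, n_sites))
    for a in range(20):
        col_counts[a] = (codes == a).sum(axis=0)
    n_site = col_counts.sum(axis=0)  # ungapped residues per column
    exp = freq[:, None] * n_site[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(exp > 0, (col_counts - exp) ** 2 / exp, 0.0)
    scores = contrib.sum(axis=0)
    scores[n_site == 0] = 0.0
    return scores


@dataclass
class TrimResult:
    alignment: Alignment
    removed_sites: np.ndarray     # original column indices, removal order
    trace: pd.DataFrame           # iteration, sites_removed, n_significant
    exhausted: bool = False       # ran out of sites before convergence

    @property
    def n_iterations(self) -> int:
        return len(self.trace)


def chi2_trim(aln: Alignment, step: float = 0.01,
              alpha: float = 0.05) -> TrimResult:
    """Iteratively trim heterogeneous sites until no taxon is significant.

    ``step`` is the fraction of the original site count removed per
    round (ceil(step * L0) sites).  Significance is P <= alpha.  Site
    ranking ties are broken by column index (leftmost removed first).
    """
    if not 0 < step < 1:
        raise ValueError("step must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    l0 = aln.n_sites
    k = math.ceil(step * l0)
    current = aln
    orig_index = np.arange(l0)
    removed: list[np.ndarray] = []
    trace_rows = []
    iteration = 0
    exhausted = False
    while True:
        if current.n_sites == 0:
            exhausted = True
            break
        n_sig = sum(r.p_value <= alpha for r in composition_tests(current))
        if n_sig == 0:
            break
        iteration += 1
        scores = site_scores(current)
        take = min(k, current.n_sites)
        # stable argsort on (-score, index): leftmost wins ties
        order = np.argsort(-scores, kind="stable")[:take]
        order = np.sort(order)  # removal reported in column order
        removed.append(orig_index[order])
        keep = np.ones(current.n_sites, dtype=bool)
        keep[order] = False
        current = current.take_sites(np.where(keep)[0])
        orig_index = orig_index[keep]
        trace_rows.append({"iteration": iteration, "sites_removed": take,
                           "n_significant": n_sig})
    trace = pd.DataFrame(trace_rows,
                         columns=["iteration", "sites_removed", "n_significant"])
    removed_idx = (np.concatenate(removed) if removed
                   else np.empty(0, dtype=int))
    return TrimResult(current, removed_idx, trace, exhausted)
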