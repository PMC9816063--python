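"""Genome quality filtering and representative selection.

Assembles the analysis dataset from externally computed genome metadata:
completeness/contamination (CheckM-style percentages) or redundancy
(duplicated single-copy markers, a ratio >= 1), plus a precomputed
dereplication cluster id.  Lineage-specific quality filters are applied
first; one representative per cluster is then kept by genome quality
score, GQS = completeness(%) - 5 * contamination(%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["GenomeRecord", "gqs_score", "filter_genomes",
           "select_representative", "select_dataset"]

CHLAMYDIAL = "chlamydial"
OTHER_PVC = "other-PVC"


@dataclass(frozen=True)
class GenomeRecord:
    id: str
    completeness: float          # percent, 0-100 (fractions accepted: 0-1)
    contamination: float = 0.0   # percent, >= 0
    redundancy: float | None = None  # ratio >= 1, chlamydial records only
    cluster: str | None = None
    lineage: str = OTHER_PVC

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"{self.id}: completeness out of [0, 100]")
        if self.contamination < 0:
            raise ValueError(f"{self.id}: negative contamination")

    @property
    def completeness_pct(self) -> float:
        """Completeness on the percent scale whichever way it was given."""
        c = self.completeness
        return c * 100.0 if c <= 1.0 else c


def gqs_score(completeness: float, contamination: float) -> float:
    """Genome quality score: completeness(%) - 5 * contamination(%)."""
    if not 0 <= completeness <= 100:
        raise ValueError("completeness out of [0, 100]")
    if contamination < 0:
        raise ValueError("negative contamination")
    return completeness - 5.0 * contamination


def filter_genomes(records: list[GenomeRecord],
                   lineage: str | None = None) -> list[GenomeRecord]:
    """Lineage-appropriate quality filter (thresholds inclusive).

    other-PVC records pass with completeness >= 90% and contamination
    <= 2%; chlamydial records pass with completeness >= 90% and marker
    redundancy <= 1.02.  With ``lineage`` given, only records of that
    lineage are considered; otherwise each record is judged by its own
    lineage tag.
    """
    out = []
    for rec in records:
        if lineage is not None and rec.lineage != lineage:
            continue
        if rec.lineage == CHLAMYDIAL:
            if rec.redundancy is None:
                raise ValueError(f"{rec.id}: chlamydial record lacks redundancy")
            if rec.completeness_pct >= 90.0 and rec.redundancy <= 1.02:
                out.append(rec)
        else:
            if rec.completeness_pct >= 90.0 and rec.contamination <= 2.0:
                out.append(rec)
    return out


def select_representative(cluster: list[GenomeRecord]) -> GenomeRecord:
    """Highest-GQS genome of a cluster; ties go to the smallest id."""
    if not cluster:
        raise ValueError("empty cluster")
    return min(
        cluster,
        key=lambda r: (-gqs_score(r.completeness_pct, r.contamination), r.id),
    )


def select_dataset(records: list[GenomeRecord]) -> pd.DataFrame:
    """Filter, then pick one representative per dereplication cluster.

    Records without a cluster id are treated as their own singleton
    clusters.  Returns a table of kept representatives with their GQS.
    """
    kept = filter_genomes(records)
    clusters: dict[str, list[GenomeRecord]] = {}
    for rec in kept:
        clusters.setdefault(rec.cluster or rec.id, []).append(rec)
    rows = []
    for cid in sorted(clusters):
        rep = select_representative(clusters[cid])
        rows.append({
            "id": rep.id,
            "cluster": cid,
            "lineage": rep.lineage,
            "completeness": rep.completeness_pct,
            "contamination": rep.contamination,
            "gqs": gqs_score(rep.completeness_pct, rep.contamination),
        })
    return pd.DataFrame(rows, columns=["id", "cluster", "lineage",
                                       "completeness", "contamination", "gqs"])


def read_genome_table(path) -> list[GenomeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "cluster": str})
    recs = []
    for row in df.itertuples(index=False):
        red = getattr(row, "redundancy", None)
        if red is not None and isinstance(red, float) and math.isnan(red):
            red = None
        recs.append(GenomeRecord(
            id=row.id,
            completeness=float(row.completeness),
            contamination=float(getattr(row, "contamination", 0.0) or 0.0),
            redundancy=red,
            cluster=getattr(row, "cluster", None),
            lineage=getattr(row, "lineage", OTHER_PVC),
        ))
    return recs
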