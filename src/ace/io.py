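"""Alignments, event tables and run configuration.

All tabular interchange is TSV with a header row; trees are Newick
(:mod:`ace.trees`) and alignments are aligned FASTA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import Tree

__all__ = [
    "AMINO_ACIDS", "Alignment", "EventTable", "FamilyProfile", "RunConfig",
    "read_alignment", "write_alignment",
    "read_event_table", "write_event_table",
    "read_family_table", "write_family_table",
    "read_gene_trees", "write_gene_trees",
]

#: Canonical residue order used for all composition vectors.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class Alignment:
    """Equal-length amino-acid rows indexed by unique taxon ids.

    ``matrix`` holds one byte per residue; gaps (``-``, ``.``) and
    ambiguity codes are retained verbatim but excluded from all
    composition counts.
    """

    ids: list[str]
    matrix: np.ndarray  # (n_taxa, n_sites) dtype 'S1'

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxon ids in alignment")
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("alignment matrix shape does not match ids")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.ids.index(taxon)]

    @classmethod
    def from_dict(cls, rows: dict[str, str]) -> "Alignment":
        ids = list(rows)
        lengths = {len(s) for s in rows.values()}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")
        mat = np.array([list(rows[i].upper().encode()) for i in ids],
                       dtype=np.uint8).view("S1") if rows else np.empty((0, 0), "S1")
        mat = mat.reshape(len(ids), -1)
        return cls(ids, mat)

    def to_dict(self) -> dict[str, str]:
        return {i: self.matrix[k].tobytes().decode()
                for k, i in enumerate(self.ids)}

    def take_sites(self, idx: np.ndarray) -> "Alignment":
        return Alignment(list(self.ids), self.matrix[:, idx])

    def residue_codes(self) -> np.ndarray:
        """(n_taxa, n_sites) int matrix: 0..19 for residues, -1 otherwise."""
        flat = self.matrix.view(np.uint8)
        codes = np.full(flat.shape, -1, dtype=np.int8)
        for aa, i in _AA_INDEX.items():
            codes[flat == ord(aa)] = i
        return codes


def read_alignment(path) -> Alignment:
    rows = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate taxon id: {rec.id!r}")
        rows[rec.id] = str(rec.seq)
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return Alignment.from_dict(rows)


def write_alignment(aln: Alignment, path) -> None:
    recs = [SeqRecord(Seq(seq), id=tid, description="")
            for tid, seq in aln.to_dict().items()]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class FamilyProfile:
    """Gene-family membership plus an optional gene-tree sample.

    ``members`` are (sequence id, genome id) pairs; copy numbers follow
    from the member counts per genome.  Families with at most one
    member are singletons and carry no gene tree.
    """

    family: str
    members: list[tuple[str, str]]
    gene_trees: list[Tree] = field(default_factory=list)

    def __post_init__(self) -> None:
        seqs = [s for s, _ in self.members]
        if len(set(seqs)) != len(seqs):
            raise ValueError(f"{self.family!r}: duplicate sequence ids")

    @property
    def is_singleton(self) -> bool:
        return len(self.members) <= 1

    def copy_numbers(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, genome in self.members:
            counts[genome] = counts.get(genome, 0) + 1
        return counts

    def seq_to_genome(self) -> dict[str, str]:
        return dict(self.members)


def read_family_table(path) -> list[FamilyProfile]:
    """TSV with header family, sequence, genome -> one profile per family."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    profiles = []
    for fam, sub in df.groupby("family", sort=True):
        members = list(zip(sub["sequence"], sub["genome"]))
        profiles.append(FamilyProfile(str(fam), members))
    return profiles


def write_family_table(profiles: list[FamilyProfile], path) -> None:
    rows = [{"family": p.family, "sequence": s, "genome": g}
            for p in profiles for s, g in p.members]
    pd.DataFrame(rows, columns=["family", "sequence", "genome"]).to_csv(
        path, sep="\t", index=False)


def read_gene_trees(path) -> list[Tree]:
    """Multi-Newick file (one tree per line) -> list of trees."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(Tree.from_newick(line))
    return trees


def write_gene_trees(trees: list[Tree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


_EVENT_COLS = ["family", "node", "O", "D", "T", "L", "C"]


@dataclass
class EventTable:
    """Per (family, species node) event and copy frequencies.

    ``provenance`` distinguishes raw reconciliation frequencies from
    tables already passed through the confident-event quantization;
    presence calls and proteome sizes are only defined on raw tables.
    """

    df: pd.DataFrame
    provenance: str = "raw"  # raw | quantized

    def __post_init__(self) -> None:
        missing = [c for c in _EVENT_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        if self.provenance not in ("raw", "quantized"):
            raise ValueError(f"bad provenance: {self.provenance!r}")
        num = self.df[["O", "D", "T", "L", "C"]].to_numpy(dtype=float)
        if np.any(num < 0) or np.any(~np.isfinite(num)):
            raise ValueError("event frequencies must be finite and >= 0")
        if self.provenance == "quantized" and np.any(num != np.round(num)):
            raise ValueError("quantized table contains non-integer values")
        self.df = self.df[_EVENT_COLS].reset_index(drop=True)

    def validate_nodes(self, tree: Tree) -> None:
        unknown = set(self.df["node"]) - set(tree.names)
        if unknown:
            raise ValueError(f"unknown species nodes: {sorted(unknown)}")

    def node_sums(self) -> pd.DataFrame:
        """Per-node event sums over families (O/D/T/L/C columns)."""
        return self.df.groupby("node")[["O", "D", "T", "L", "C"]].sum()


def read_event_table(path, tree: Tree | None = None,
                     provenance: str = "raw") -> EventTable:
    df = pd.read_csv(path, sep="\t", dtype={"family": str, "node": str})
    tab = EventTable(df, provenance)
    if tree is not None:
        tab.validate_nodes(tree)
    return tab


def write_event_table(tab: EventTable, path) -> None:
    tab.df.to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Pipeline-wide thresholds, costs and seeds (JSON round-trippable)."""

    seed: int = 0
    frequency_cutoff: float = 0.3   # tau: presence / confident-event cutoff
    alpha: float = 0.05             # significance level (chi2, highways)
    presence_fraction: float = 0.5  # complex-presence rule
    trim_step: float = 0.01         # chi2-trimming increment (of input sites)
    dup_cost: float = 2.0
    transfer_cost: float = 3.0
    loss_cost: float = 1.0
    gain_penalty: float = 1.0       # Wagner parsimony per-copy gain cost
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.frequency_cutoff <= 1:
            raise ValueError("frequency_cutoff must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if min(self.dup_cost, self.transfer_cost, self.loss_cost) <= 0:
            raise ValueError("event costs must be > 0")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
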