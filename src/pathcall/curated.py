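"""Characterized-protein database: loading, clustering, heteromer flagging.

Characterized (experimentally validated) proteins anchor every confidence
call: a candidate is believed to perform a step only by similarity to
proteins known to perform it, weighed against similarity to proteins with
other functions. Records come from a protein FASTA plus a TSV of
annotations (protein_id, source, description, comma-separated step ids,
is_complex). Proteins with no step associations are "other-function"
context, used only to demote over-similar candidates.

The curation-support clustering groups characterized sequences into
single-linkage components at 30% identity and 75% alignment coverage of
both sequences (defaults), which is how step definitions and transporter
families are assembled and over-merged permease subunits are detected
(those are usually re-clustered at 40% identity).
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
from Bio import SeqIO

__all__ = [
    "CuratedProtein",
    "ClusterConfig",
    "CuratedDB",
    "load_curated",
    "cluster_curated",
    "flag_heteromers",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")
HETEROMER_KEYWORDS = ("subunit", "component")


@dataclass
class CuratedProtein:
    """A characterized sequence with its step associations and source tag."""

    protein_id: str
    sequence: str
    description: str = ""
    source: str = ""
    step_ids: list[str] = field(default_factory=list)
    is_complex: bool = False

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal residues {sorted(bad)} "
                "(allowed: 20 amino acids plus X)"
            )


@dataclass
class ClusterConfig:
    """Identity/coverage thresholds for curation-support clustering."""

    min_identity: float = 0.30
    min_coverage_both: float = 0.75

    def __post_init__(self):
        for name in ("min_identity", "min_coverage_both"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]: {v}")


class CuratedDB(dict):
    """Mapping protein_id -> CuratedProtein with step and source indexes.

    Backed by a plain dict for in-memory use; ``to_sqlite``/``from_sqlite``
    give an indexed on-disk form for repeated runs against large databases.
    """

    def by_step(self, step_id: str) -> list[CuratedProtein]:
        return [p for p in self.values() if step_id in p.step_ids]

    def counts_by_source(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.values():
            counts[p.source] = counts.get(p.source, 0) + 1
        return dict(sorted(counts.items()))

    # -- persistence ----------------------------------------------------
    _SCHEMA = """
        CREATE TABLE proteins (
            protein_id TEXT PRIMARY KEY,
            sequence TEXT NOT NULL,
            description TEXT,
            source TEXT,
            step_ids TEXT,
            is_complex INTEGER
        );
        CREATE TABLE protein_steps (
            protein_id TEXT,
            step_id TEXT,
            PRIMARY KEY (protein_id, step_id)
        );
        CREATE INDEX idx_step ON protein_steps (step_id);
    """

    def to_sqlite(self, path: str | Path) -> None:
        con = sqlite3.connect(path)
        try:
            con.executescript("DROP TABLE IF EXISTS proteins; DROP TABLE IF EXISTS protein_steps;")
            con.executescript(self._SCHEMA)
            for p in self.values():
                con.execute(
                    "INSERT INTO proteins VALUES (?,?,?,?,?,?)",
                    (p.protein_id, p.sequence, p.description, p.source,
                     ",".join(p.step_ids), int(p.is_complex)),
                )
                con.executemany(
                    "INSERT INTO protein_steps VALUES (?,?)",
                    [(p.protein_id, s) for s in p.step_ids],
                )
            con.commit()
        finally:
            con.close()

    @classmethod
    def from_sqlite(cls, path: str | Path) -> "CuratedDB":
        con = sqlite3.connect(path)
        try:
            db = cls()
            for row in con.execute(
                "SELECT protein_id, sequence, description, source, step_ids, is_complex "
                "FROM proteins ORDER BY protein_id"
            ):
                pid, seq, desc, source, steps, is_complex = row
                db[pid] = CuratedProtein(
                    protein_id=pid, sequence=seq, description=desc or "",
                    source=source or "",
                    step_ids=[s for s in (steps or "").split(",") if s],
                    is_complex=bool(is_complex),
                )
            return db
        finally:
            con.close()


def load_curated(fasta, annotations) -> CuratedDB:
    """Build a CuratedDB from a protein FASTA and an annotation TSV.

    ``fasta`` and ``annotations`` may be paths or open text handles. Every
    annotation row must reference a FASTA record; FASTA records without an
    annotation row are kept as unannotated other-function proteins.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(fasta, "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()

    db = CuratedDB()
    handle = open(annotations) if isinstance(annotations, (str, Path)) else annotations
    try:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"annotation row needs 5 columns: {line!r}")
            pid, source, desc, steps, is_complex = fields[:5]
            if pid not in sequences:
                raise ValueError(f"annotation references absent FASTA id {pid!r}")
            if pid in db:
                raise ValueError(f"duplicate annotation for {pid!r}")
            db[pid] = CuratedProtein(
                protein_id=pid,
                sequence=sequences[pid],
                description=desc,
                source=source,
                step_ids=[s for s in steps.split(",") if s],
                is_complex=is_complex.strip() == "1",
            )
    finally:
        if isinstance(annotations, (str, Path)):
            handle.close()
    for pid, seq in sequences.items():
        if pid not in db:
            db[pid] = CuratedProtein(protein_id=pid, sequence=seq)
    return db


def cluster_curated(
    proteins: Iterable[CuratedProtein], config: ClusterConfig | None = None
) -> list[list[str]]:
    """Single-linkage clusters of characterized proteins.

    An edge joins two proteins when their best local alignment reaches
    ``min_identity`` and covers at least ``min_coverage_both`` of BOTH
    sequences; clusters are the connected components, sorted by size
    (descending) then by lexicographic leader. The identity definition is
    the homology module's (one contract everywhere).
    """
    from .homology import align_pair  # deferred: homology imports this module

    config = config or ClusterConfig()
    prots = sorted(proteins, key=lambda p: p.protein_id)
    graph = nx.Graph()
    graph.add_nodes_from(p.protein_id for p in prots)
    for i, a in enumerate(prots):
        for b in prots[i + 1:]:
            aln = align_pair(a.sequence, b.sequence, max_evalue=None)
            if (
                aln is not None
                and aln.identity >= config.min_identity
                and aln.query_coverage >= config.min_coverage_both
                and aln.subject_coverage >= config.min_coverage_both
            ):
                graph.add_edge(a.protein_id, b.protein_id)
    clusters = [sorted(c) for c in nx.connected_components(graph)]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def flag_heteromers(proteins: Iterable[CuratedProtein]) -> dict[str, bool]:
    """True for proteins likely to be one subunit of a multi-protein complex.

    A protein is flagged when its record carries an explicit complex
    annotation or its description mentions "subunit" or "component"
    (case-insensitive).
    """
    flags: dict[str, bool] = {}
    for p in proteins:
        desc = p.description.lower()
        flags[p.protein_id] = p.is_complex or any(k in desc for k in HETEROMER_KEYWORDS)
    return flags
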