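"""Deaminase homolog mining: motif filtering, redundancy removal, representatives.

Candidate dsDNA cytidine deaminases are screened for the two zinc-binding
motifs required for catalysis — the literal ``HVE`` tripeptide and a
``CxxC`` pair of cysteines two residues apart.  Motif-positive candidates
are then collapsed by CD-HIT-style greedy incremental clustering: records
are visited longest-first, and each either joins the first cluster whose
representative it matches at or above the identity threshold or founds a
new cluster.  Representative selection at a lower threshold (default 0.80)
picks one protein per >=80%-identity group.

Identity here is global-alignment identity: matched columns divided by all
alignment columns (gaps included), with match 1, mismatch 0 and a linear
gap penalty.  This is an exact pairwise computation, not CD-HIT's k-mer
screening heuristic; the two agree except for sequences sitting close to
the threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_HVE = re.compile(r"(?=HVE)")
_CXXC = re.compile(r"(?=C..C)")


@dataclass(frozen=True)
class ProteinRecord:
    """A candidate deaminase (id conventionally the 4-letter accession suffix)."""

    id: str
    sequence: str
    source_tax: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("protein sequence must be non-empty")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid residues in {self.id}: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHits:
    hve_positions: tuple[int, ...]
    cxxc_positions: tuple[int, ...]

    @property
    def has_both(self) -> bool:
        return bool(self.hve_positions) and bool(self.cxxc_positions)


def scan_motifs(record: ProteinRecord) -> MotifHits:
    """All (possibly overlapping) HVE and CxxC occurrences, 0-based offsets."""
    seq = record.sequence
    return MotifHits(
        hve_positions=tuple(m.start() for m in _HVE.finditer(seq)),
        cxxc_positions=tuple(m.start() for m in _CXXC.finditer(seq)),
    )


def filter_candidates(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Keep records carrying both zinc-binding motifs, preserving input order."""
    return [r for r in records if scan_motifs(r).has_both]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Global-alignment identity: matches / alignment columns, in [0, 1]."""
    if not a.sequence or not b.sequence:
        raise ValueError("sequences must be non-empty")
    aln = _ALIGNER.align(a.sequence, b.sequence)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns


@dataclass
class Cluster:
    representative: ProteinRecord
    members: list[ProteinRecord] = field(default_factory=list)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float

    @property
    def representatives(self) -> list[ProteinRecord]:
        return [c.representative for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)


def greedy_cluster(records: list[ProteinRecord], threshold: float) -> ClusterSet:
    """CD-HIT-style greedy incremental clustering.

    Records are sorted by length descending (ties broken by id); each joins
    the first existing cluster whose *representative* it matches at identity
    >= threshold, otherwise it founds a new cluster.  Deterministic.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    clusters: list[Cluster] = []
    for rec in ordered:
        for cl in clusters:
            if pairwise_identity(rec, cl.representative) >= threshold:
                cl.members.append(rec)
                break
        else:
            clusters.append(Cluster(representative=rec, members=[rec]))
    return ClusterSet(clusters, threshold)


def select_representatives(records: list[ProteinRecord],
                           threshold: float = 0.80) -> list[ProteinRecord]:
    """One representative per >=threshold-identity group (greedy clustering)."""
    return greedy_cluster(records, threshold).representatives


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def screen_table(records: list[ProteinRecord],
                 cluster_threshold: float = 0.90,
                 representative_threshold: float = 0.80):
    """Run the full funnel and return (table, retained, representatives).

    The table has one row per input record with motif counts, cluster id and
    representative flag (clustering/representative columns only for
    motif-positive records).
    """
    import pandas as pd

    retained = filter_candidates(records)
    clusters = greedy_cluster(retained, cluster_threshold)
    nonredundant = clusters.representatives
    reps = select_representatives(nonredundant, representative_threshold)
    rep_ids = {r.id for r in reps}
    cluster_of = {
        m.id: i for i, cl in enumerate(clusters.clusters) for m in cl.members
    }
    rows = []
    for r in records:
        hits = scan_motifs(r)
        rows.append({
            "id": r.id,
            "length": len(r),
            "hve_count": len(hits.hve_positions),
            "cxxc_count": len(hits.cxxc_positions),
            "motif_positive": hits.has_both,
            "cluster_id": cluster_of.get(r.id, -1),
            "is_representative": r.id in rep_ids,
        })
    return pd.DataFrame(rows), nonredundant, reps
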