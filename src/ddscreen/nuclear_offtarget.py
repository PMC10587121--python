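"""Nuclear off-target candidate prediction by approximate TALE-site matching.

A DdCBE pair binds a left and a right TALE site separated by a spacer of
roughly the on-target length; a nuclear locus highly homologous to that
arrangement is a candidate off-target.  The matcher scans both strands of
each contig for placements where the left and the right site each match
within a per-site Hamming mismatch cap and are separated by a spacer length
inside the configured range (right site downstream of the left on the same
strand, matching the editor geometry).  Substitution-only matching is
deliberate: candidate loci of interest are near-duplicates, and a
deterministic mismatch cap replaces a local-alignment engine.

Flanking sequence (default 500 bp each side, clipped at contig ends) is
exported so assay primers can be designed externally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import encode, revcomp, validate_dna


@dataclass(frozen=True)
class TaleQuery:
    left_site: str
    right_site: str
    spacer_len_min: int
    spacer_len_max: int
    max_mismatch_fraction: float = 0.20

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_site",
                           validate_dna(self.left_site, "left_site"))
        object.__setattr__(self, "right_site",
                           validate_dna(self.right_site, "right_site"))
        if self.spacer_len_min > self.spacer_len_max or self.spacer_len_min < 0:
            raise ValueError("invalid spacer length range")
        if not (0 <= self.max_mismatch_fraction < 1):
            raise ValueError("max_mismatch_fraction must be in [0, 1)")

    @classmethod
    def from_target(cls, left_site: str, right_site: str, spacer_len: int,
                    spacer_slack: int = 4,
                    max_mismatch_fraction: float = 0.20) -> "TaleQuery":
        """Query around a known on-target spacer length (+/- slack)."""
        return cls(left_site, right_site,
                   max(0, spacer_len - spacer_slack), spacer_len + spacer_slack,
                   max_mismatch_fraction)


@dataclass(frozen=True)
class NuclearHit:
    """One candidate locus: [start, end) spans left site through right site."""

    contig: str
    start: int
    end: int
    strand: str
    left_mismatches: int
    right_mismatches: int
    spacer_len: int
    flank_up: str = ""
    flank_down: str = ""

    @property
    def total_mismatches(self) -> int:
        return self.left_mismatches + self.right_mismatches


def _mismatch_profile(contig_idx: np.ndarray, pattern: str) -> np.ndarray:
    """Hamming mismatches of ``pattern`` at every offset of the contig."""
    p = encode(pattern)
    n_off = len(contig_idx) - len(p) + 1
    if n_off <= 0:
        return np.zeros(0, dtype=np.int64)
    mm = np.zeros(n_off, dtype=np.int64)
    for j, base in enumerate(p):
        mm += contig_idx[j:j + n_off] != base
    return mm


def _scan_strand(contig_idx: np.ndarray, query: TaleQuery) -> list[tuple[int, int, int, int, int]]:
    """(start, end, left_mm, right_mm, spacer_len) tuples on one strand."""
    llen, rlen = len(query.left_site), len(query.right_site)
    lcap = int(query.max_mismatch_fraction * llen)
    rcap = int(query.max_mismatch_fraction * rlen)
    lmm = _mismatch_profile(contig_idx, query.left_site)
    rmm = _mismatch_profile(contig_idx, query.right_site)
    left_hits = np.flatnonzero(lmm <= lcap)
    right_ok = rmm <= rcap
    out = []
    for ls in left_hits:
        for spacer in range(query.spacer_len_min, query.spacer_len_max + 1):
            rs = ls + llen + spacer
            if rs < len(right_ok) and right_ok[rs]:
                out.append((int(ls), int(rs + rlen), int(lmm[ls]),
                            int(rmm[rs]), spacer))
    return out


def find_homologous_sites(contigs: dict[str, str] | str | Path,
                          query: TaleQuery) -> list[NuclearHit]:
    """All two-site placements within the mismatch caps, both strands.

    Minus-strand hits are found by scanning the reverse complement and are
    reported in plus-strand half-open coordinates.  Hits are sorted by total
    mismatches, then (contig, start).
    """
    if isinstance(contigs, (str, Path)):
        contigs = {r.id: str(r.seq).upper()
                   for r in SeqIO.parse(str(contigs), "fasta")}
    hits: list[NuclearHit] = []
    for name, seq in contigs.items():
        seq = validate_dna(seq, f"contig {name}")
        n = len(seq)
        fwd = encode(seq)
        for strand, idx in (("+", fwd), ("-", encode(revcomp(seq)))):
            for s, e, lmm, rmm, sp in _scan_strand(idx, query):
                if strand == "-":
                    s, e = n - e, n - s
                hits.append(NuclearHit(name, s, e, strand, lmm, rmm, sp))
    return sorted(hits, key=lambda h: (h.total_mismatches, h.contig, h.start,
                                       h.strand))


def extract_flanks(hit: NuclearHit, contigs: dict[str, str],
                   flank: int = 500) -> tuple[str, str]:
    """(upstream, downstream) reference-strand flanks, clipped at contig ends."""
    seq = contigs[hit.contig]
    up = seq[max(0, hit.start - flank):hit.start]
    down = seq[hit.end:hit.end + flank]
    return up, down


def annotate_flanks(hits: list[NuclearHit], contigs: dict[str, str],
                    flank: int = 500) -> list[NuclearHit]:
    out = []
    for h in hits:
        up, down = extract_flanks(h, contigs, flank)
        out.append(replace(h, flank_up=up, flank_down=down))
    return out


def hits_to_frame(hits: list[NuclearHit]) -> pd.DataFrame:
    cols = ["contig", "start", "end", "strand", "left_mismatches",
            "right_mismatches", "spacer_len", "flank_up", "flank_down"]
    return pd.DataFrame([vars(h) for h in hits], columns=cols)


def write_hits_bed(hits: list[NuclearHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(f"{h.contig}\t{h.start}\t{h.end}\thit_{i + 1}\t"
                     f"{h.total_mismatches}\t{h.strand}\n")
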