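"""Amplicon-read quantification: demultiplex, align, pile up, call edited sites.

Reads are assigned to library members by exact barcode match at the read
start, placed on their amplicon by best gapless offset (the amplicons have a
fixed structure, so substitution-only placement suffices; reads whose best
placement still exceeds the mismatch cap are rejected and counted), piled up
per position, and summarized per annotated cytosine site as a C->T (plus
strand) or G->A (minus-strand C) conversion frequency.

The default frequency denominator is the total non-N depth at the position;
a reference+converted-only denominator ("ct") is available, since published
pipelines differ on this point.  Sites below ``min_depth`` are flagged
rather than dropped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import encode
from .library_design import Amplicon, CSite, SpacerLibrary

_BASE_COL = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def read_fastq_seqs(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a (possibly gzipped) FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq.upper()


@dataclass
class ReadBin:
    """Reads assigned to one amplicon by exact barcode prefix match."""

    amplicon_id: str
    reads: list[str] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return len(self.reads)


@dataclass
class DemuxResult:
    bins: list[ReadBin]
    n_unassigned: int

    @property
    def n_assigned(self) -> int:
        return sum(b.n_assigned for b in self.bins)


def demultiplex(reads: Iterable[str] | str | Path,
                library: SpacerLibrary) -> DemuxResult:
    """Assign each read to the amplicon whose barcode it starts with."""
    if isinstance(reads, (str, Path)):
        reads = read_fastq_seqs(reads)
    barcode_map = library.barcode_map  # raises on duplicates at build time
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ValueError("library barcodes must share one length")
    blen = lengths.pop()
    bins = {a.id: ReadBin(a.id) for a in library}
    unassigned = 0
    for seq in reads:
        amp = barcode_map.get(seq[:blen].upper())
        if amp is None:
            unassigned += 1
        else:
            bins[amp.id].reads.append(seq.upper())
    return DemuxResult(list(bins.values()), unassigned)


@dataclass(frozen=True)
class AlignedRead:
    offset: int
    mismatches: int


def align_read(read: str, amplicon: Amplicon,
               max_mismatch_fraction: float = 0.10) -> AlignedRead | None:
    """Best gapless placement of ``read`` on the amplicon, or None if rejected.

    The read must fit inside the reference; among all offsets the one with
    the fewest mismatches wins (ties to the smallest offset), and the read
    is rejected when the mismatch fraction exceeds the cap.
    """
    ref = encode(amplicon.full_seq)
    q = encode(read.upper())
    if len(q) > len(ref):
        return None
    best = _best_offset(q, ref)
    if best is None:
        return None
    offset, mm = best
    if mm > max_mismatch_fraction * len(q):
        return None
    return AlignedRead(offset, mm)


def _best_offset(q: np.ndarray, ref: np.ndarray) -> tuple[int, int] | None:
    n_off = len(ref) - len(q) + 1
    if n_off <= 0:
        return None
    best_off, best_mm = 0, len(q) + 1
    for off in range(n_off):
        mm = int(np.count_nonzero(ref[off:off + len(q)] != q))
        if mm < best_mm:
            best_off, best_mm = off, mm
            if mm == 0:
                break
    return best_off, best_mm


@dataclass
class PileupCounts:
    """Per-position A/C/G/T/N counts over a reference."""

    counts: np.ndarray  # (length, 5) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 5:
            raise ValueError("counts must be (length, 5)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        """Non-N depth per position."""
        return self.counts[:, :4].sum(axis=1)

    def base_count(self, base: str) -> np.ndarray:
        return self.counts[:, _BASE_COL[base]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=["A", "C", "G", "T", "N"])
        df.insert(0, "position", np.arange(len(self)))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PileupCounts":
        df = df.sort_values("position")
        if not (df["position"].to_numpy() == np.arange(len(df))).all():
            raise ValueError("pileup positions must be contiguous from 0")
        return cls(df[["A", "C", "G", "T", "N"]].to_numpy())


def pileup_bin(bin_: ReadBin, amplicon: Amplicon,
               max_mismatch_fraction: float = 0.10) -> tuple[PileupCounts, int]:
    """Pile up one bin's reads on the amplicon; returns (pileup, n_rejected).

    Reads matching the reference length are mismatch-checked at offset 0 in
    one vectorized pass (the common case for fixed-structure amplicons);
    anything else falls back to the per-read offset scan.
    """
    ref = encode(amplicon.full_seq)
    L = len(ref)
    counts = np.zeros((L, 5), dtype=np.int64)
    rejected = 0
    full_len = [r for r in bin_.reads if len(r) == L]
    other = [r for r in bin_.reads if len(r) != L]
    if full_len:
        mat = np.frombuffer("".join(full_len).encode("ascii"),
                            dtype=np.uint8).reshape(len(full_len), L)
        from ._seq import BASE_INDEX
        mat = BASE_INDEX[mat]
        mm = np.count_nonzero(mat != ref[None, :], axis=1)
        ok = mm <= max_mismatch_fraction * L
        rejected += int(np.count_nonzero(~ok))
        keep = mat[ok]
        for col in range(L):
            counts[col] += np.bincount(keep[:, col], minlength=5)
    for read in other:
        hit = align_read(read, amplicon, max_mismatch_fraction)
        if hit is None:
            rejected += 1
            continue
        q = encode(read)
        np.add.at(counts, (np.arange(hit.offset, hit.offset + len(q)), q), 1)
    return PileupCounts(counts), rejected


@dataclass(frozen=True)
class SiteCall:
    """Quantified conversion at one annotated cytosine site."""

    position: int
    strand: str
    context: str
    depth: int
    converted: int
    frequency: float  # nan when depth == 0
    low_depth: bool

    @property
    def nc_context(self) -> str:
        return self.context + "C"


@dataclass
class EditingProfile:
    """Per-cytosine editing frequencies for one sample x amplicon."""

    amplicon_id: str
    sites: list[SiteCall]
    n_assigned: int = 0
    n_rejected: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "amplicon_id": self.amplicon_id,
            "position": s.position,
            "strand": s.strand,
            "context": s.context,
            "depth": s.depth,
            "converted": s.converted,
            "frequency": s.frequency,
            "low_depth": s.low_depth,
        } for s in self.sites])


def _site_call(site: CSite, pile: PileupCounts, min_depth: int,
               denominator: str) -> SiteCall:
    converted_base = "T" if site.strand == "+" else "A"
    ref_base = "C" if site.strand == "+" else "G"
    conv = int(pile.base_count(converted_base)[site.position])
    if denominator == "depth":
        denom = int(pile.depth[site.position])
    elif denominator == "ct":
        denom = conv + int(pile.base_count(ref_base)[site.position])
    else:
        raise ValueError("denominator must be 'depth' or 'ct'")
    freq = conv / denom if denom > 0 else float("nan")
    return SiteCall(site.position, site.strand, site.context,
                    denom, conv, freq, denom < min_depth)


def quantify(bins: list[ReadBin] | DemuxResult, library: SpacerLibrary,
             max_mismatch_fraction: float = 0.10, min_depth: int = 100,
             denominator: str = "depth") -> list[EditingProfile]:
    """C->T / G->A conversion frequency at every annotated site of every bin."""
    if isinstance(bins, DemuxResult):
        bins = bins.bins
    profiles = []
    for bin_ in bins:
        amp = library.get(bin_.amplicon_id)  # KeyError on unknown id
        pile, rejected = pileup_bin(bin_, amp, max_mismatch_fraction)
        sites = [_site_call(s, pile, min_depth, denominator) for s in amp.c_sites]
        profiles.append(EditingProfile(amp.id, sites, bin_.n_assigned, rejected))
    return profiles


def call_edited_sites(profile: EditingProfile,
                      threshold: float = 0.01,
                      require_depth: bool = True) -> set[SiteCall]:
    """Sites whose conversion frequency strictly exceeds the threshold."""
    return {
        s for s in profile.sites
        if np.isfinite(s.frequency) and s.frequency > threshold
        and not (require_depth and s.low_depth)
    }


def profiles_to_frame(profiles: list[EditingProfile],
                      threshold: float = 0.01) -> pd.DataFrame:
    """Long-format table over profiles with an edited flag per site."""
    frames = []
    for p in profiles:
        df = p.to_frame()
        df["edited"] = (df["frequency"] > threshold) & ~df["low_depth"]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["amplicon_id", "position", "strand",
                                     "context", "depth", "converted",
                                     "frequency", "low_depth", "edited"])
    return pd.concat(frames, ignore_index=True)
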