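"""Whole-mtDNA off-target characterization on a circular genome.

From a per-position pileup over the (circular) mitochondrial reference, every
reference C gets a C->T frequency and every reference G a G->A frequency (a
reference G is a C on the minus strand).  Pre-existing variants are masked
using untreated-control samples: any C/G whose conversion rate exceeds 1% in
a control is a SNP, and the mask is the union over controls.  Off-target
sites (OTS) are then the unmasked, off-window sites above the 1% threshold.

Summaries: the average off-target rate (mean frequency over all unmasked,
covered C/G sites), pairwise OTS-set overlaps, Spearman correlation between
samples over the union of their OTS with average-linkage clustering, and an
11-position base-probability matrix of OTS flanking context (minus-strand
sites reverse-complemented so the edited base reads C at the center).

Coordinates are 0-based internally; reports use the 1-based "m." convention
of mitochondrial nomenclature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from Bio import SeqIO

from ._seq import revcomp, validate_dna
from .amplicon_quant import PileupCounts

Site = tuple[int, str]  # (0-based position, strand)


@dataclass
class CircularGenome:
    """A (typically circular) reference; flank extraction wraps the origin."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = validate_dna(self.sequence, "genome sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Slice [start, end); out-of-range coordinates wrap when circular."""
        width = end - start
        n = len(self.sequence)
        if width < 0 or width > n:
            raise ValueError("invalid slice width")
        if not self.circular:
            if start < 0 or end > n:
                raise IndexError("slice outside a linear genome")
            return self.sequence[start:end]
        start %= n
        return (self.sequence + self.sequence)[start:start + width]

    @classmethod
    def from_fasta(cls, path: str | Path, circular: bool = True) -> "CircularGenome":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(rec.id, str(rec.seq), circular)


@dataclass
class MtEditingMap:
    """Per-C/G-site conversion frequencies over one genome, one sample."""

    genome_name: str
    positions: np.ndarray      # 0-based reference positions of C/G sites
    strands: np.ndarray        # "+" for reference C, "-" for reference G
    frequencies: np.ndarray    # nan where depth == 0
    depths: np.ndarray
    on_target_region: tuple[int, int] | None = None  # 0-based half-open

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.strands) == len(self.frequencies) == len(self.depths) == n):
            raise ValueError("site arrays must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def sites(self) -> list[Site]:
        return list(zip(self.positions.tolist(), self.strands.tolist()))

    def frequency_of(self) -> dict[Site, float]:
        return {s: f for s, f in zip(self.sites, self.frequencies.tolist())}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions,
            "label": [f"m.{p + 1}" for p in self.positions],
            "strand": self.strands,
            "depth": self.depths,
            "frequency": self.frequencies,
        })


def mt_frequencies(pileup: PileupCounts, genome: CircularGenome,
                   on_target_region: tuple[int, int] | None = None) -> MtEditingMap:
    """C->T / G->A frequency at every reference C/G position of the genome."""
    if len(pileup) != len(genome):
        raise ValueError("pileup length does not match genome length")
    seq = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    is_c = seq == ord("C")
    is_g = seq == ord("G")
    positions = np.flatnonzero(is_c | is_g)
    strands = np.where(is_c[positions], "+", "-")
    depth = pileup.depth[positions]
    conv = np.where(is_c[positions],
                    pileup.base_count("T")[positions],
                    pileup.base_count("A")[positions])
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, conv / np.maximum(depth, 1), np.nan)
    return MtEditingMap(genome.name, positions, strands, freq,
                        depth, on_target_region)


def snp_mask(control_maps: MtEditingMap | list[MtEditingMap],
             threshold: float = 0.01) -> set[Site]:
    """Sites with conversion rate above threshold in any control sample."""
    if isinstance(control_maps, MtEditingMap):
        control_maps = [control_maps]
    mask: set[Site] = set()
    for m in control_maps:
        above = np.isfinite(m.frequencies) & (m.frequencies > threshold)
        mask |= {s for s, a in zip(m.sites, above.tolist()) if a}
    return mask


def _in_region(pos: np.ndarray, region: tuple[int, int] | None) -> np.ndarray:
    if region is None:
        return np.zeros(len(pos), dtype=bool)
    lo, hi = region
    return (pos >= lo) & (pos < hi)


def call_otss(sample_map: MtEditingMap, mask: set[Site],
              on_target_region: tuple[int, int] | None = None,
              threshold: float = 0.01) -> set[Site]:
    """Unmasked, off-window C/G sites with frequency strictly above threshold."""
    region = on_target_region or sample_map.on_target_region
    above = np.isfinite(sample_map.frequencies) & (sample_map.frequencies > threshold)
    off_window = ~_in_region(sample_map.positions, region)
    return {
        s for s, a, ok in zip(sample_map.sites, above.tolist(), off_window.tolist())
        if a and ok and s not in mask
    }


def average_offtarget_rate(sample_map: MtEditingMap, mask: set[Site],
                           on_target_region: tuple[int, int] | None = None,
                           ots_only: bool = False,
                           threshold: float = 0.01) -> float:
    """Mean conversion frequency over eligible sites.

    By default the denominator is every unmasked, covered C/G site outside
    the on-target window; ``ots_only=True`` averages over called OTS instead.
    """
    region = on_target_region or sample_map.on_target_region
    eligible = (np.isfinite(sample_map.frequencies)
                & ~_in_region(sample_map.positions, region))
    masked = np.fromiter((s in mask for s in sample_map.sites),
                         dtype=bool, count=len(sample_map))
    eligible &= ~masked
    if ots_only:
        ots = call_otss(sample_map, mask, region, threshold)
        eligible &= np.fromiter((s in ots for s in sample_map.sites),
                                dtype=bool, count=len(sample_map))
    if not eligible.any():
        return float("nan")
    return float(sample_map.frequencies[eligible].mean())


@dataclass(frozen=True)
class OverlapReport:
    n_a: int
    n_b: int
    n_shared: int
    coverage_a: float  # |a & b| / |a|
    coverage_b: float  # |a & b| / |b|


def ots_overlap(a: set[Site], b: set[Site]) -> OverlapReport:
    shared = len(a & b)
    return OverlapReport(
        n_a=len(a), n_b=len(b), n_shared=shared,
        coverage_a=shared / len(a) if a else float("nan"),
        coverage_b=shared / len(b) if b else float("nan"),
    )


@dataclass
class CorrelationResult:
    labels: list[str]
    matrix: pd.DataFrame       # Spearman rho, unit diagonal
    leaf_order: list[str]      # average-linkage order on 1 - rho


def editing_correlation(samples: list[MtEditingMap],
                        ots_sets: list[set[Site]] | None = None,
                        labels: list[str] | None = None,
                        mask: set[Site] | None = None,
                        threshold: float = 0.01) -> CorrelationResult:
    """Spearman correlation between samples over the union of their OTS.

    ``ots_sets`` may be precomputed; otherwise each sample's OTS are called
    against ``mask`` (default empty) at ``threshold``.  Frequencies are taken
    from each sample at every union site (0 where uncovered).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    labels = labels or [f"sample_{i + 1}" for i in range(len(samples))]
    if ots_sets is None:
        ots_sets = [call_otss(m, mask or set(), threshold=threshold)
                    for m in samples]
    union = sorted(set().union(*ots_sets))
    if not union:
        raise ValueError("no OTS in any sample")
    X = np.zeros((len(samples), len(union)))
    for i, m in enumerate(samples):
        lookup = m.frequency_of()
        X[i] = [0.0 if not np.isfinite(lookup.get(s, 0.0)) else lookup.get(s, 0.0)
                for s in union]
    rho = spearmanr(X, axis=1).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-sample case
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    matrix = pd.DataFrame(rho, index=labels, columns=labels)
    dist = squareform(np.clip(1.0 - rho, 0.0, None), checks=False)
    order = leaves_list(linkage(dist, method="average"))
    return CorrelationResult(labels, matrix, [labels[i] for i in order])


def motif_matrix(ots: set[Site], genome: CircularGenome,
                 flank: int = 5) -> pd.DataFrame:
    """Base-probability matrix of OTS flanking sequence, -flank..+flank.

    Minus-strand (reference G) sites are reverse-complemented so every row
    of extracted sequence reads 5'->3' on the edited strand with C at the
    center.  Rows are positions, columns A/C/G/T; each row sums to 1.
    """
    if not ots:
        raise ValueError("empty OTS set")
    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=np.int64)
    col = {"A": 0, "C": 1, "G": 2, "T": 3}
    for pos, strand in sorted(ots):
        window = genome.fetch(pos - flank, pos + flank + 1)
        if strand == "-":
            window = revcomp(window)
        if window[flank] != "C":
            raise ValueError(f"site ({pos}, {strand}) is not a reference C/G")
        for i, base in enumerate(window):
            counts[i, col[base]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(probs, index=range(-flank, flank + 1),
                        columns=["A", "C", "G", "T"])


def read_pileup_tsv(path: str | Path) -> PileupCounts:
    return PileupCounts.from_frame(pd.read_csv(path, sep="\t"))


def write_ots_bed(ots: set[Site], freqs: dict[Site, float],
                  genome_name: str, path: str | Path) -> None:
    """OTS as BED6 (0-based half-open, score = frequency)."""
    with open(path, "w") as fh:
        for pos, strand in sorted(ots):
            fh.write(f"{genome_name}\t{pos}\t{pos + 1}\tm.{pos + 1}\t"
                     f"{freqs.get((pos, strand), 0.0):.6f}\t{strand}\n")
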