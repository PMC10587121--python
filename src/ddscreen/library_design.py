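"""Saturated spacer-library design for characterizing dsDNA cytidine deaminases.

The screening construct places a variable spacer between two fixed TALE
recognition sites, with a 4-nt barcode upstream of the left site for
demultiplexing.  Spacers are six tandem copies of a cytosine-containing
triplet, partitioned into three subsets by the position of a fixed C:

* ``NNC`` — C fixed at triplet position 3 (15 triplets; CCC excluded because
  homopolymeric C runs are error-prone in amplification/sequencing),
* ``NCN`` — C at position 2, position 3 not C (12 triplets),
* ``CNN`` — C at position 1, positions 2 and 3 not C (9 triplets).

Together the 36 triplets cover every C-containing triplet except CCC, so the
library saturates all NC dinucleotide contexts of a target cytosine.  Two
user-supplied locus spacers (e.g. JAK2/SIRT6 analogues, positive controls in
the screen) complete the 38-member library.

The module also enumerates split x orientation editor pairs (each candidate
deaminase is halved at two sites and each half rides the left or right TALE,
giving four pairs per protein) and builds the editing-window plasmid suite
used to place a target C/G at a range of distances from a fixed TALE site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import complement, validate_dna

SUBSETS = ("NNC", "NCN", "CNN")

#: Synthetic stand-in TALE recognition sites; real screens supply their own.
#: Any non-empty, C/G-annotatable sites work.
DEFAULT_LEFT_TALE = "TCCTTGGACTTGTCCA"
DEFAULT_RIGHT_TALE = "TGGAGTCATTGACCTA"

#: Synthetic stand-ins for the JAK2/SIRT6 positive-control spacers
#: (the published spacer sequences are not bundled; these only mimic length
#: and mixed C/G content).
SYNTHETIC_LOCUS_SPACERS = {
    "JAK2_synthetic": "TTGTGGACAACAGTCAAACAACAATTT",
    "SIRT6_synthetic": "AGGCCGTCTGGACACCATCTTT",
}


@dataclass(frozen=True)
class Triplet:
    """A 3-nt spacer building block containing at least one C (never CCC)."""

    bases: str
    subset: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", validate_dna(self.bases, "triplet"))
        if len(self.bases) != 3:
            raise ValueError("triplet must be exactly 3 nt")
        if "C" not in self.bases:
            raise ValueError("triplet must contain at least one C")
        if self.bases == "CCC":
            raise ValueError("CCC is excluded from the library")
        if self.subset != classify_triplet(self.bases):
            raise ValueError(
                f"triplet {self.bases} belongs to subset "
                f"{classify_triplet(self.bases)}, not {self.subset}"
            )


def classify_triplet(bases: str) -> str:
    """Assign a C-containing triplet to NNC / NCN / CNN.

    Subsets claim triplets in NNC -> NCN -> CNN order, so a triplet with C at
    position 3 is always NNC, one with C at position 2 (but not 3) is NCN,
    and CNN takes only triplets whose sole C is at position 1.
    """
    if "C" not in bases or bases == "CCC":
        raise ValueError(f"{bases} is not a library triplet")
    if bases[2] == "C":
        return "NNC"
    if bases[1] == "C":
        return "NCN"
    return "CNN"


def enumerate_spacer_triplets(subset: str) -> list[Triplet]:
    """All triplets of one subset, deduplicated and lexicographically sorted."""
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")
    out = []
    for combo in itertools.product("ACGT", repeat=3):
        bases = "".join(combo)
        if "C" not in bases or bases == "CCC":
            continue
        if classify_triplet(bases) == subset:
            out.append(Triplet(bases, subset))
    return sorted(out, key=lambda t: t.bases)


def all_library_triplets() -> list[Triplet]:
    """The full 36-triplet union, NNC then NCN then CNN, each sorted."""
    return [t for s in SUBSETS for t in enumerate_spacer_triplets(s)]


@dataclass(frozen=True)
class SpacerRecord:
    """One library member: a spacer sequence plus its demultiplexing barcode."""

    id: str
    barcode: str
    spacer_seq: str
    origin: str  # "triplet" | "locus"
    triplet: Triplet | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcode", validate_dna(self.barcode, "barcode"))
        object.__setattr__(
            self, "spacer_seq", validate_dna(self.spacer_seq, "spacer_seq")
        )
        if self.origin not in ("triplet", "locus"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.origin == "triplet":
            if self.triplet is None:
                raise ValueError("triplet spacers need a Triplet")
            n = len(self.spacer_seq) // 3
            if self.spacer_seq != self.triplet.bases * n:
                raise ValueError("spacer is not a tandem repeat of its triplet")


def build_spacer(triplet: Triplet, repeats: int = 6, barcode: str = "AAAA",
                 id: str | None = None) -> SpacerRecord:
    """Tandem-repeat spacer from one triplet (default six copies)."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    return SpacerRecord(
        id=id or f"{triplet.subset}_{triplet.bases}",
        barcode=barcode,
        spacer_seq=triplet.bases * repeats,
        origin="triplet",
        triplet=triplet,
    )


@dataclass(frozen=True)
class CSite:
    """An editable cytosine in an amplicon.

    ``position`` is a 0-based offset into the amplicon full sequence.  A
    reference G is a C on the minus strand; its ``context`` is the base 5' of
    the C on that (edited) strand, i.e. the complement of the base 3' of the
    G on the reference.
    """

    position: int
    strand: str  # "+" (reference C) | "-" (reference G)
    context: str  # single 5'-adjacent base on the edited strand

    @property
    def nc_context(self) -> str:
        return self.context + "C"


@dataclass(frozen=True)
class Amplicon:
    """barcode + left TALE site + spacer + right TALE site (+ fixed flanks)."""

    spacer: SpacerRecord
    left_tale: str
    right_tale: str
    full_seq: str
    c_sites: tuple[CSite, ...]
    spacer_start: int
    spacer_end: int

    @property
    def id(self) -> str:
        return self.spacer.id


def annotate_c_sites(full_seq: str, start: int, end: int) -> tuple[CSite, ...]:
    """Annotate every C (+ strand) and G (- strand C) in ``full_seq[start:end]``."""
    sites = []
    for i in range(start, end):
        base = full_seq[i]
        if base == "C":
            sites.append(CSite(i, "+", full_seq[i - 1]))
        elif base == "G":
            sites.append(CSite(i, "-", complement(full_seq[i + 1])))
    return tuple(sites)


def make_amplicon(spacer: SpacerRecord, left_tale: str, right_tale: str,
                  flank5: str = "", flank3: str = "") -> Amplicon:
    """Assemble the amplicon and annotate spacer-region C/G sites."""
    left_tale = validate_dna(left_tale, "left_tale")
    right_tale = validate_dna(right_tale, "right_tale")
    prefix = (flank5.upper() if flank5 else "") + spacer.barcode + left_tale
    full_seq = prefix + spacer.spacer_seq + right_tale + (flank3.upper() if flank3 else "")
    start = len(prefix)
    end = start + len(spacer.spacer_seq)
    return Amplicon(
        spacer=spacer,
        left_tale=left_tale,
        right_tale=right_tale,
        full_seq=full_seq,
        c_sites=annotate_c_sites(full_seq, start, end),
        spacer_start=start,
        spacer_end=end,
    )


def assign_barcodes(n: int, length: int = 4, seed: int = 0,
                    exclude: Iterable[str] = ()) -> list[str]:
    """``n`` distinct random barcodes of the given length, seed-deterministic.

    ``exclude`` removes barcodes that must not be used (e.g. the first
    ``length`` nt of the left TALE site, which would confuse exact-prefix
    demultiplexing).
    """
    capacity = 4 ** length
    excluded = {validate_dna(b, "excluded barcode") for b in exclude}
    if n > capacity - len(excluded):
        raise ValueError(
            f"cannot draw {n} distinct {length}-mers (capacity {capacity}, "
            f"{len(excluded)} excluded)"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(capacity)
    out: list[str] = []
    for code in order:
        bases = "".join("ACGT"[(code >> (2 * k)) & 3] for k in range(length))
        if bases in excluded:
            continue
        out.append(bases)
        if len(out) == n:
            break
    return out


@dataclass
class SpacerLibrary:
    """The barcoded amplicon collection screened in one transfection."""

    amplicons: list[Amplicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate amplicon ids in library")
        barcodes = [a.spacer.barcode for a in self.amplicons]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in library")

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def get(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    @property
    def barcode_map(self) -> dict[str, Amplicon]:
        return {a.spacer.barcode: a for a in self.amplicons}

    @property
    def n_c_sites(self) -> int:
        return sum(len(a.c_sites) for a in self.amplicons)

    def to_manifest(self) -> pd.DataFrame:
        rows = []
        for a in self.amplicons:
            t = a.spacer.triplet
            rows.append({
                "id": a.id,
                "barcode": a.spacer.barcode,
                "subset": t.subset if t else "",
                "triplet": t.bases if t else "",
                "spacer_seq": a.spacer.spacer_seq,
                "full_seq": a.full_seq,
                "origin": a.spacer.origin,
                "left_tale": a.left_tale,
                "right_tale": a.right_tale,
            })
        return pd.DataFrame(rows)

    def write(self, fasta_path: str | Path, manifest_path: str | Path) -> None:
        records = [
            SeqRecord(Seq(a.full_seq), id=a.id, description="")
            for a in self.amplicons
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        self.to_manifest().to_csv(manifest_path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta_path: str | Path, manifest_path: str | Path) -> "SpacerLibrary":
        manifest = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
        amplicons = []
        for row in manifest.itertuples(index=False):
            triplet = Triplet(row.triplet, row.subset) if row.origin == "triplet" else None
            spacer = SpacerRecord(row.id, row.barcode, row.spacer_seq,
                                  row.origin, triplet)
            amp = make_amplicon(spacer, row.left_tale, row.right_tale)
            if row.id not in seqs:
                raise ValueError(f"{row.id} missing from FASTA")
            if seqs[row.id] != amp.full_seq or row.full_seq != amp.full_seq:
                raise ValueError(f"sequence mismatch for {row.id}")
            amplicons.append(amp)
        return cls(amplicons)


def build_library(left_tale: str = DEFAULT_LEFT_TALE,
                  right_tale: str = DEFAULT_RIGHT_TALE,
                  locus_spacers: dict[str, str] | None = None,
                  seed: int = 0,
                  repeats: int = 6,
                  barcode_length: int = 4) -> SpacerLibrary:
    """The saturated library: 36 triplet spacers plus any locus spacers.

    ``locus_spacers`` maps id -> spacer sequence; pass
    :data:`SYNTHETIC_LOCUS_SPACERS` for the bundled JAK2/SIRT6 stand-ins.
    """
    left_tale = validate_dna(left_tale, "left_tale")
    right_tale = validate_dna(right_tale, "right_tale")
    locus = locus_spacers or {}
    triplets = all_library_triplets()
    n = len(triplets) + len(locus)
    barcodes = assign_barcodes(n, barcode_length, seed,
                               exclude=[left_tale[:barcode_length]])
    spacers = [
        build_spacer(t, repeats, barcode=bc)
        for t, bc in zip(triplets, barcodes)
    ]
    for (lid, seq), bc in zip(locus.items(), barcodes[len(triplets):]):
        spacers.append(SpacerRecord(lid, bc, seq, "locus"))
    return SpacerLibrary([make_amplicon(s, left_tale, right_tale) for s in spacers])


@dataclass(frozen=True)
class EditorPair:
    """One deaminase split half-pair: protein x split site x orientation."""

    protein_id: str
    split_site: str
    orientation: str  # "NC" | "CN" (which terminal half rides the left TALE)


def enumerate_editor_pairs(protein_ids: Sequence[str],
                           splits_per_protein: int | Sequence[str] = 2,
                           orientations: int | Sequence[str] = 2) -> list[EditorPair]:
    """Cross every protein with its split sites and orientations.

    Split/orientation labels may be given explicitly; integer counts generate
    generic labels (orientation count 2 uses the conventional NC/CN).
    """
    if isinstance(splits_per_protein, int):
        if splits_per_protein < 1:
            raise ValueError("splits_per_protein must be >= 1")
        splits = [f"split{i + 1}" for i in range(splits_per_protein)]
    else:
        splits = list(splits_per_protein)
    if isinstance(orientations, int):
        if orientations < 1:
            raise ValueError("orientations must be >= 1")
        orients = ["NC", "CN"] if orientations == 2 else [
            f"orient{i + 1}" for i in range(orientations)
        ]
    else:
        orients = list(orientations)
    return [
        EditorPair(pid, s, o)
        for pid in protein_ids for s in splits for o in orients
    ]


@dataclass
class WindowSuite:
    """Editing-window amplicons placing one target C/G at varied TALE distances."""

    windows: list[Amplicon]
    target_index: list[int]  # per-window position of the target in full_seq

    def __post_init__(self) -> None:
        for amp, t in zip(self.windows, self.target_index):
            if amp.full_seq[t] not in "CG":
                raise ValueError(f"target index {t} of {amp.id} is not C/G")


def build_window_suite(tale_site: str,
                       window_core: str,
                       target_offset_in_core: int,
                       n_windows: int = 10,
                       right_tale: str = DEFAULT_RIGHT_TALE,
                       seed: int = 0) -> WindowSuite:
    """Slide a fixed-length window over ``window_core`` across ``n_windows`` shifts.

    Window i is ``window_core[i : i + L]`` with ``L = len(core) - n_windows + 1``,
    so the target base sits at ``n_windows`` distinct distances from the fixed
    left TALE site.  The target must be C or G and fall inside every window.
    """
    tale_site = validate_dna(tale_site, "tale_site")
    core = validate_dna(window_core, "window_core")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    width = len(core) - n_windows + 1
    if width < 1:
        raise ValueError("window_core too short for n_windows")
    if core[target_offset_in_core] not in "CG":
        raise ValueError("target base must be C or G")
    if not (n_windows - 1 <= target_offset_in_core < width):
        raise ValueError(
            "target would fall outside some windows; need "
            f"{n_windows - 1} <= target_offset_in_core < {width}"
        )
    barcodes = assign_barcodes(n_windows, 4, seed, exclude=[tale_site[:4]])
    windows, targets = [], []
    for i in range(n_windows):
        spacer = SpacerRecord(f"window_{i + 1:02d}", barcodes[i],
                              core[i:i + width], "locus")
        amp = make_amplicon(spacer, tale_site, right_tale)
        windows.append(amp)
        targets.append(amp.spacer_start + target_offset_in_core - i)
    return WindowSuite(windows, targets)
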