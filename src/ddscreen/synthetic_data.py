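"""Synthetic ground-truth generators for every pipeline stage.

An :class:`EditorModel` captures the phenomenology being screened for: a
per-NC-context base editing rate, optional positional window weights across
the spacer, and a strand factor, giving each annotated cytosine an effective
conversion rate ``context_weight * window_weight * strand_factor``.  From a
model the module simulates barcoded amplicon reads (independent per-site
binomial conversion plus uniform substitution error at constant quality) and
whole-mtDNA pileups with planted heteroplasmic SNPs and off-target sites.
Ground truth is emitted alongside every simulation so recovery tests can
compare pipeline estimates against planted rates.

Shipped editor presets mimic the qualitative preference classes seen among
dsDNA deaminases (TC-preferring canonical-like, GC-preferring,
AC-compatible); their rate values are invented, not measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import INDEX_BASE, complement, encode
from .amplicon_quant import PileupCounts
from .homolog_screen import ProteinRecord
from .library_design import Amplicon, SpacerLibrary
from .mtdna_offtarget import CircularGenome, Site

_ERR_OFFDIAG = None  # built lazily in _error_matrix


@dataclass(frozen=True)
class EditorModel:
    """Simulation ground truth for one deaminase editor."""

    label: str
    context_weights: dict[str, float]  # {"AC","CC","GC","TC"} -> rate in [0,1]
    window_weights: tuple[float, ...] | None = None  # per spacer offset; None = flat
    strand_bias: float = 1.0  # multiplier applied to minus-strand (G) sites

    def __post_init__(self) -> None:
        missing = {"AC", "CC", "GC", "TC"} - set(self.context_weights)
        if missing:
            raise ValueError(f"missing context weights: {sorted(missing)}")
        for ctx, w in self.context_weights.items():
            if not (0 <= w <= 1):
                raise ValueError(f"context weight {ctx}={w} outside [0, 1]")
        if not (0 <= self.strand_bias <= 1):
            raise ValueError("strand_bias must be in [0, 1]")
        if self.window_weights is not None:
            ws = tuple(float(w) for w in self.window_weights)
            if any(not (0 <= w <= 1) for w in ws):
                raise ValueError("window weights must be in [0, 1]")
            object.__setattr__(self, "window_weights", ws)

    def site_rate(self, nc_context: str, spacer_offset: int,
                  strand: str) -> float:
        w = self.context_weights[nc_context]
        if self.window_weights is not None:
            idx = min(spacer_offset, len(self.window_weights) - 1)
            w *= self.window_weights[idx]
        if strand == "-":
            w *= self.strand_bias
        return w


#: Invented preset models covering the qualitative preference classes.
EDITOR_PRESETS = {
    "tc_canonical": EditorModel(
        "tc_canonical", {"TC": 0.30, "AC": 0.01, "CC": 0.01, "GC": 0.005}),
    "gc_editor": EditorModel(
        "gc_editor", {"GC": 0.25, "TC": 0.10, "AC": 0.03, "CC": 0.02}),
    "ac_editor": EditorModel(
        "ac_editor", {"AC": 0.20, "TC": 0.15, "CC": 0.02, "GC": 0.01}),
    "null": EditorModel("null", {"AC": 0.0, "CC": 0.0, "GC": 0.0, "TC": 0.0}),
}


def effective_site_rates(amplicon: Amplicon, editor: EditorModel) -> list[float]:
    """Planted conversion rate for each annotated c_site of the amplicon."""
    return [
        editor.site_rate(s.nc_context, s.position - amplicon.spacer_start,
                         s.strand)
        for s in amplicon.c_sites
    ]


def expected_observed_frequency(rate: float, error_rate: float) -> float:
    """Closed-form frequency the pipeline should recover at infinite depth.

    The converted base is observed when the site converted and no error hit
    it, or when an unconverted base erred into the converted base:
    ``r (1 - e) + (1 - r) e / 3``.
    """
    return rate * (1 - error_rate) + (1 - rate) * error_rate / 3


@dataclass
class SimulationTruth:
    """Planted per-site rates (and mtDNA SNP/OTS plants) plus the seed used."""

    seed: int
    depth: int
    error_rate: float
    library_rates: dict[str, list[dict]] = field(default_factory=dict)
    ots: list[dict] = field(default_factory=list)
    snps: list[dict] = field(default_factory=list)
    ots_shortfall: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(vars(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_library_reads(library: SpacerLibrary, editor: EditorModel,
                           depth: int = 5000, error_rate: float = 1e-3,
                           seed: int = 0,
                           fastq_path: str | Path | None = None,
                           ) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Simulate ``depth`` reads per amplicon under an editor model.

    Each annotated C/G converts independently at its effective rate (C->T on
    the plus strand, G->A for minus-strand cytosines); uniform substitution
    error is then applied to every base.  Returns ``(reads, truth)`` with
    reads as (read_id, sequence) pairs, and writes a constant-quality FASTQ
    when ``fastq_path`` is given.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 <= error_rate <= 0.1):
        raise ValueError("error_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed, depth=depth, error_rate=error_rate)
    reads: list[tuple[str, str]] = []
    for amp in library:
        ref = encode(amp.full_seq)
        mat = np.tile(ref, (depth, 1))
        rates = effective_site_rates(amp, editor)
        truth.library_rates[amp.id] = [
            {"position": s.position, "strand": s.strand,
             "context": s.nc_context, "rate": r,
             "expected_frequency": expected_observed_frequency(r, error_rate)}
            for s, r in zip(amp.c_sites, rates)
        ]
        for site, rate in zip(amp.c_sites, rates):
            if rate <= 0:
                continue
            hit = rng.random(depth) < rate
            mat[hit, site.position] = 3 if site.strand == "+" else 0  # T or A
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            n_err = int(err.sum())
            if n_err:
                mat[err] = (mat[err] + rng.integers(1, 4, n_err)) % 4
        seqs = INDEX_BASE[mat]
        for i in range(depth):
            reads.append((f"{amp.id}_read{i + 1}",
                          seqs[i].tobytes().decode("ascii")))
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads, truth


def synthetic_mt_genome(length: int = 16569, gc: float = 0.44,
                        seed: int = 0, name: str = "synthetic_mt",
                        ) -> CircularGenome:
    """A random circular genome stand-in matching mtDNA length and GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p).astype(np.uint8)
    return CircularGenome(name, INDEX_BASE[idx].tobytes().decode("ascii"))


def _cg_sites(genome: CircularGenome) -> list[Site]:
    return [(i, "+" if b == "C" else "-")
            for i, b in enumerate(genome.sequence) if b in "CG"]


def _site_context(genome: CircularGenome, site: Site) -> str:
    pos, strand = site
    if strand == "+":
        return genome.fetch(pos - 1, pos) + "C"
    return complement(genome.fetch(pos + 1, pos + 2)) + "C"


def _error_matrix(e: float) -> np.ndarray:
    E = np.full((4, 4), e / 3)
    np.fill_diagonal(E, 1 - e)
    return E


def simulate_mt_pileup(genome: CircularGenome,
                       n_ots: int = 50,
                       ots_rate_range: tuple[float, float] = (0.05, 0.30),
                       snps: Sequence[tuple[int, float]] = (),
                       depth: int = 5000,
                       error_rate: float = 1e-3,
                       seed: int = 0,
                       ots_context: str | None = None,
                       ) -> tuple[PileupCounts, PileupCounts, SimulationTruth]:
    """Control and treated whole-genome pileups with planted SNPs and OTS.

    SNPs (pre-existing variants at the given heteroplasmy) appear in both
    pileups; OTS appear only in the treated one, sampled without replacement
    from C/G sites (optionally restricted to one NC context, e.g. ``"TC"``).
    If fewer eligible sites exist than requested, the shortfall is recorded
    in the truth rather than raised.
    """
    lo, hi = ots_rate_range
    if not (0.01 < lo <= hi <= 1):
        raise ValueError("ots_rate_range must satisfy 0.01 < lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    L = len(genome)
    seq_idx = encode(genome.sequence)
    snp_positions = {p for p, _ in snps}
    for pos, het in snps:
        if genome.sequence[pos] not in "CG":
            raise ValueError(f"SNP position {pos} is not a C/G")
        if not (0 < het <= 1):
            raise ValueError("heteroplasmy must be in (0, 1]")
    candidates = [s for s in _cg_sites(genome) if s[0] not in snp_positions]
    if ots_context is not None:
        candidates = [s for s in candidates
                      if _site_context(genome, s) == ots_context]
    planted = min(n_ots, len(candidates))
    chosen = [candidates[i] for i in
              rng.choice(len(candidates), size=planted, replace=False)]
    rates = rng.uniform(lo, hi, size=planted)

    truth = SimulationTruth(seed=seed, depth=depth, error_rate=error_rate,
                            ots_shortfall=n_ots - planted)
    truth.snps = [{"position": int(p), "strand":
                   "+" if genome.sequence[p] == "C" else "-",
                   "heteroplasmy": float(h)} for p, h in snps]
    truth.ots = [{"position": int(p), "strand": st, "rate": float(r)}
                 for (p, st), r in zip(chosen, rates)]

    def _pileup(site_rates: dict[int, float]) -> PileupCounts:
        p_pre = np.zeros((L, 4))
        p_pre[np.arange(L), seq_idx] = 1.0
        for pos, rate in site_rates.items():
            ref = seq_idx[pos]
            alt = 3 if ref == 1 else 0  # C->T or G->A
            p_pre[pos, ref] = 1 - rate
            p_pre[pos, alt] = rate
        p_obs = p_pre @ _error_matrix(error_rate)
        counts4 = rng.multinomial(depth, p_obs)
        return PileupCounts(np.hstack([counts4,
                                       np.zeros((L, 1), dtype=np.int64)]))

    snp_rates = {int(p): float(h) for p, h in snps}
    control = _pileup(dict(snp_rates))
    treated_rates = dict(snp_rates)
    treated_rates.update({int(p): float(r)
                          for (p, _), r in zip(chosen, rates)})
    treated = _pileup(treated_rates)
    return control, treated, truth


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def simulate_homolog_set(n_families: int = 6,
                         members_per_family: int = 3,
                         n_motif_negative: int = 5,
                         length: int = 140,
                         within_family_divergence: float = 0.05,
                         seed: int = 0,
                         ) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Deaminase-like protein records with known family structure.

    Each family founder is a random sequence carrying planted HVE and CxxC
    motifs; members are point-mutated copies (motifs preserved).  Motif-
    negative decoys lack both motifs.  Returns ``(records, family_of_id)``
    with decoys labelled family ``-1``.
    """
    if length < 20:
        raise ValueError("length must be >= 20 to place both motifs")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    families: dict[str, int] = {}

    def random_seq(n: int, forbid_motifs: bool) -> str:
        while True:
            s = "".join(rng.choice(list(_AA20), size=n))
            if not forbid_motifs or ("HVE" not in s and _no_cxxc(s)):
                return s

    def _no_cxxc(s: str) -> bool:
        return all(not (s[i] == "C" and s[i + 3] == "C")
                   for i in range(len(s) - 3))

    for fam in range(n_families):
        base = list(random_seq(length, forbid_motifs=True))
        hve_at = int(rng.integers(2, length // 2 - 4))
        base[hve_at:hve_at + 3] = "HVE"
        cxxc_at = int(rng.integers(length // 2, length - 5))
        base[cxxc_at] = "C"
        base[cxxc_at + 3] = "C"
        protected = set(range(hve_at, hve_at + 3)) | {cxxc_at, cxxc_at + 3}
        for m in range(members_per_family):
            seq = list(base)
            if m > 0:
                n_mut = max(1, int(within_family_divergence * length))
                sites = [i for i in
                         rng.choice(length, size=3 * n_mut, replace=False)
                         if i not in protected][:n_mut]
                for i in sites:
                    seq[i] = rng.choice([a for a in _AA20 if a != seq[i]])
            rid = f"FAM{fam:02d}_{m:02d}"
            records.append(ProteinRecord(rid, "".join(seq)))
            families[rid] = fam
    for d in range(n_motif_negative):
        rid = f"NEG{d:02d}"
        records.append(ProteinRecord(rid, random_seq(length, forbid_motifs=True)))
        families[rid] = -1
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, families
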