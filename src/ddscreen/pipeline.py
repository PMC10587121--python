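"""End-to-end orchestration: design -> simulate/ingest -> quantify -> report.

A :class:`RunConfig` carries every path, threshold and seed of a run and is
serialized next to the outputs, so a report bundle always records the exact
configuration that produced it.  :func:`run_characterize` executes the
screen's in-silico analogue (library design, read simulation or ingestion,
quantification, context summaries, optional mtDNA off-target analysis) and
:func:`run_screen` executes the homolog-mining funnel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .amplicon_quant import demultiplex, profiles_to_frame, quantify
from .context_stats import summarize_contexts
from .homolog_screen import read_protein_fasta, screen_table
from .library_design import (
    SYNTHETIC_LOCUS_SPACERS,
    DEFAULT_LEFT_TALE,
    DEFAULT_RIGHT_TALE,
    build_library,
    enumerate_editor_pairs,
)
from .mtdna_offtarget import (
    average_offtarget_rate,
    call_otss,
    motif_matrix,
    mt_frequencies,
    snp_mask,
    write_ots_bed,
)
from .synthetic_data import (
    EDITOR_PRESETS,
    EditorModel,
    simulate_library_reads,
    simulate_mt_pileup,
    synthetic_mt_genome,
)


@dataclass
class RunConfig:
    outdir: str = "ddscreen_run"
    seed: int = 0
    left_tale: str = DEFAULT_LEFT_TALE
    right_tale: str = DEFAULT_RIGHT_TALE
    locus_spacers: dict = field(default_factory=lambda: dict(SYNTHETIC_LOCUS_SPACERS))
    editor: str | dict = "gc_editor"
    depth: int = 2000
    error_rate: float = 1e-3
    edited_threshold: float = 0.01
    snp_threshold: float = 0.01
    min_depth: int = 100
    max_mismatch_fraction: float = 0.10
    reads_fastq: str | None = None  # ingest instead of simulating when set
    mtdna: dict | None = None       # e.g. {"n_ots": 50, "depth": 5000, ...}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _editor_from_config(cfg: RunConfig) -> EditorModel:
    if isinstance(cfg.editor, str):
        if cfg.editor not in EDITOR_PRESETS:
            raise ValueError(f"unknown editor preset {cfg.editor!r}; "
                             f"choose from {sorted(EDITOR_PRESETS)}")
        return EDITOR_PRESETS[cfg.editor]
    return EditorModel(cfg.editor.get("label", "custom"),
                       cfg.editor["context_weights"],
                       tuple(cfg.editor["window_weights"])
                       if cfg.editor.get("window_weights") else None,
                       cfg.editor.get("strand_bias", 1.0))


def run_characterize(config: RunConfig) -> dict:
    """Full characterization run; returns the output index (also written)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    index: dict = {"version": __version__, "config_digest": config.digest(),
                   "seed": config.seed, "outputs": {}}

    library = build_library(config.left_tale, config.right_tale,
                            config.locus_spacers, seed=config.seed)
    library.write(out / "library.fasta", out / "library_manifest.tsv")
    index["outputs"]["library_fasta"] = "library.fasta"
    index["outputs"]["library_manifest"] = "library_manifest.tsv"

    if config.reads_fastq is not None:
        fastq = Path(config.reads_fastq)
        if not fastq.exists():
            raise FileNotFoundError(f"reads_fastq not found: {fastq}")
    else:
        editor = _editor_from_config(config)
        fastq = out / "reads.fastq"
        _, truth = simulate_library_reads(library, editor, config.depth,
                                          config.error_rate, config.seed,
                                          fastq_path=fastq)
        truth.to_json(out / "truth.json")
        index["outputs"]["truth"] = "truth.json"

    demux = demultiplex(fastq, library)
    profiles = quantify(demux, library, config.max_mismatch_fraction,
                        config.min_depth)
    table = profiles_to_frame(profiles, config.edited_threshold)
    table.to_csv(out / "editing.tsv", sep="\t", index=False)
    index["outputs"]["editing"] = "editing.tsv"
    index["demultiplex"] = {"assigned": demux.n_assigned,
                            "unassigned": demux.n_unassigned,
                            "rejected": sum(p.n_rejected for p in profiles)}

    summary = summarize_contexts(profiles, config.edited_threshold)
    summary.to_frame().to_csv(out / "context_summary.tsv", sep="\t", index=False)
    index["outputs"]["context_summary"] = "context_summary.tsv"
    index["n_edited_sites"] = summary.total_edited

    if config.mtdna:
        mt = dict(config.mtdna)
        genome = synthetic_mt_genome(mt.get("genome_length", 16569),
                                     seed=config.seed)
        control, treated, mt_truth = simulate_mt_pileup(
            genome,
            n_ots=mt.get("n_ots", 50),
            ots_rate_range=tuple(mt.get("ots_rate_range", (0.05, 0.30))),
            snps=[tuple(s) for s in mt.get("snps", [])],
            depth=mt.get("depth", 5000),
            error_rate=mt.get("error_rate", config.error_rate),
            seed=config.seed,
        )
        control_map = mt_frequencies(control, genome)
        treated_map = mt_frequencies(treated, genome)
        mask = snp_mask(control_map, config.snp_threshold)
        ots = call_otss(treated_map, mask, threshold=config.edited_threshold)
        write_ots_bed(ots, treated_map.frequency_of(), genome.name,
                      out / "mt_ots.bed")
        mt_truth.to_json(out / "mt_truth.json")
        summary_json = {
            "n_ots": len(ots),
            "n_snp_masked": len(mask),
            "average_offtarget_rate": average_offtarget_rate(treated_map, mask),
        }
        with open(out / "mt_summary.json", "w") as fh:
            json.dump(summary_json, fh, indent=1)
        if ots:
            motif_matrix(ots, genome).to_csv(out / "mt_motif_matrix.tsv",
                                             sep="\t")
            index["outputs"]["mt_motif_matrix"] = "mt_motif_matrix.tsv"
        index["outputs"]["mt_ots_bed"] = "mt_ots.bed"
        index["outputs"]["mt_summary"] = "mt_summary.json"
        index["outputs"]["mt_truth"] = "mt_truth.json"
        index["mtdna"] = summary_json

    config.to_yaml(out / "config.yaml")
    index["outputs"]["config"] = "config.yaml"
    with open(out / "index.json", "w") as fh:
        json.dump(index, fh, indent=1)
    return index


def run_screen(protein_fasta: str | Path, outdir: str | Path,
               cluster_threshold: float = 0.90,
               representative_threshold: float = 0.80,
               splits: int = 2, orientations: int = 2) -> dict:
    """Homolog-mining funnel: motif scan, clustering, reps, pair enumeration."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_protein_fasta(protein_fasta)
    if not records:
        raise ValueError(f"no records in {protein_fasta}")
    table, nonredundant, reps = screen_table(records, cluster_threshold,
                                             representative_threshold)
    table.to_csv(out / "screen_table.tsv", sep="\t", index=False)
    with open(out / "representatives.fasta", "w") as fh:
        for r in reps:
            fh.write(f">{r.id}\n{r.sequence}\n")
    pairs = enumerate_editor_pairs([r.id for r in reps], splits, orientations)
    import pandas as pd
    pd.DataFrame([vars(p) for p in pairs]).to_csv(
        out / "editor_pairs.tsv", sep="\t", index=False)
    summary = {
        "n_input": len(records),
        "n_motif_positive": int(table["motif_positive"].sum()),
        "n_nonredundant": len(nonredundant),
        "n_representatives": len(reps),
        "n_editor_pairs": len(pairs),
    }
    with open(out / "screen_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
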