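"""Context-preference and comparison statistics over editing profiles.

For one sample screened against the library, cytosine sites are grouped by
their NC dinucleotide context (the base 5' of the edited C: AC, CC, GC, TC)
and summarized as

* ``n_edited`` — sites with conversion frequency strictly above threshold,
* ``max_edit`` — maximum frequency over all sites in the context,
* ``mean_edit`` — mean frequency over *all* sites in the context (edited or
  not), which is what makes editors with narrow preferences comparable,
* ``proportion`` — the context's share of all edited sites.

The module also quantifies per-site inhibitor effects as
log2((f_with + p) / (f_without + p)) with a small pseudocount, and scores
editing-window suites by on-target frequency versus aggregate bystander
editing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amplicon_quant import EditingProfile, SiteCall, call_edited_sites
from .library_design import WindowSuite

NC_CONTEXTS = ("AC", "CC", "GC", "TC")


@dataclass(frozen=True)
class ContextRow:
    context: str
    n_sites: int
    n_edited: int
    max_edit: float
    mean_edit: float
    proportion: float  # nan when no site is edited in any context


@dataclass
class ContextSummary:
    rows: dict[str, ContextRow]

    def __getitem__(self, context: str) -> ContextRow:
        return self.rows[context]

    @property
    def total_edited(self) -> int:
        return sum(r.n_edited for r in self.rows.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows.values()])


def summarize_contexts(profiles: list[EditingProfile],
                       threshold: float = 0.01,
                       efficiency_weighted: bool = False) -> ContextSummary:
    """Per-NC-context editing summary over one sample's profiles.

    Proportions are count-weighted by default (each edited site counts once);
    ``efficiency_weighted=True`` weights each edited site by its frequency
    instead.
    """
    sites: list[SiteCall] = [s for p in profiles for s in p.sites]
    edited: set[SiteCall] = set()
    for p in profiles:
        edited |= call_edited_sites(p, threshold)
    weight = {True: (lambda s: s.frequency), False: (lambda s: 1.0)}[
        bool(efficiency_weighted)]
    total_weight = sum(weight(s) for s in edited)
    rows = {}
    for ctx in NC_CONTEXTS:
        ctx_sites = [s for s in sites if s.nc_context == ctx]
        freqs = [s.frequency for s in ctx_sites if math.isfinite(s.frequency)]
        ctx_edited = [s for s in edited if s.nc_context == ctx]
        rows[ctx] = ContextRow(
            context=ctx,
            n_sites=len(ctx_sites),
            n_edited=len(ctx_edited),
            max_edit=max(freqs, default=float("nan")),
            mean_edit=float(np.mean(freqs)) if freqs else float("nan"),
            proportion=(sum(weight(s) for s in ctx_edited) / total_weight
                        if total_weight > 0 else float("nan")),
        )
    return ContextSummary(rows)


@dataclass
class InhibitionReport:
    """Per-site log2 editing ratio with vs without inhibitor."""

    table: pd.DataFrame  # position, strand, context, f_with, f_without, log2_ratio
    pseudocount: float


def _site_key(s: SiteCall) -> tuple[int, str]:
    return (s.position, s.strand)


def inhibition_effect(with_profile: EditingProfile,
                      without_profile: EditingProfile,
                      pseudocount: float = 1e-4,
                      threshold: float = 0.01) -> InhibitionReport:
    """log2((f_with + p) / (f_without + p)) at sites edited without inhibitor.

    The pseudocount bounds the ratio when either frequency is zero; with the
    published metric a two-fold drop reads -1, complete inhibition reads a
    large negative value set by the pseudocount.
    """
    keys_w = {_site_key(s) for s in with_profile.sites}
    keys_wo = {_site_key(s) for s in without_profile.sites}
    if keys_w != keys_wo:
        raise ValueError("profiles cover different site sets")
    f_with = {_site_key(s): s for s in with_profile.sites}
    rows = []
    for s in sorted(call_edited_sites(without_profile, threshold),
                    key=_site_key):
        w = f_with[_site_key(s)]
        ratio = math.log2((w.frequency + pseudocount) /
                          (s.frequency + pseudocount))
        rows.append({"position": s.position, "strand": s.strand,
                     "context": s.context, "f_with": w.frequency,
                     "f_without": s.frequency, "log2_ratio": ratio})
    cols = ["position", "strand", "context", "f_with", "f_without", "log2_ratio"]
    return InhibitionReport(pd.DataFrame(rows, columns=cols), pseudocount)


@dataclass(frozen=True)
class WindowScore:
    window_id: str
    target_position: int
    on_target: float
    bystander_aggregate: float
    ratio: float
    active: bool


def score_windows(suite_profiles: list[EditingProfile],
                  suite: WindowSuite,
                  pseudocount: float = 1e-4,
                  bystander_mode: str = "sum",
                  activity_floor: float = 0.01) -> list[WindowScore]:
    """Score each editing window by on-target vs bystander conversion.

    ``bystander_aggregate`` is the sum (default; ``bystander_mode="max"`` for
    the maximum) of frequencies at all non-target C/G sites of the window.
    Windows are returned ranked by ratio, then on-target frequency.  Windows
    whose on-target frequency is below ``activity_floor`` are flagged inactive.
    """
    if bystander_mode not in ("sum", "max"):
        raise ValueError("bystander_mode must be 'sum' or 'max'")
    by_id = {a.id: t for a, t in zip(suite.windows, suite.target_index)}
    scores = []
    for profile in suite_profiles:
        if profile.amplicon_id not in by_id:
            raise ValueError(f"no target annotation for {profile.amplicon_id}")
        target_pos = by_id[profile.amplicon_id]
        on = [s.frequency for s in profile.sites if s.position == target_pos]
        if not on:
            raise ValueError(
                f"target position {target_pos} not among annotated sites of "
                f"{profile.amplicon_id}")
        others = [s.frequency for s in profile.sites
                  if s.position != target_pos and math.isfinite(s.frequency)]
        agg = (sum(others) if bystander_mode == "sum"
               else max(others, default=0.0))
        ratio = on[0] / (agg + pseudocount)
        scores.append(WindowScore(profile.amplicon_id, target_pos, on[0],
                                  agg, ratio, on[0] >= activity_floor))
    return sorted(scores, key=lambda w: (-w.ratio, -w.on_target))
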