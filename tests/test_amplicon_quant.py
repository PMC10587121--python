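"""Demultiplexing, gapless placement, and frequency recovery against
binomial/closed-form oracles."""

import numpy as np
import pytest

from ddscreen.amplicon_quant import (
    align_read,
    call_edited_sites,
    demultiplex,
    pileup_bin,
    quantify,
    ReadBin,
)
from ddscreen.library_design import build_library
from ddscreen.synthetic_data import EditorModel, simulate_library_reads


@pytest.fixture(scope="module")
def small_library():
    lib = build_library(seed=5)
    # a handful of amplicons covering all four NC contexts
    keep = {"NNC_ACC", "NNC_GCC", "NNC_TCC", "NCN_ACA", "CNN_CAA"}
    from ddscreen.library_design import SpacerLibrary
    return SpacerLibrary([a for a in lib if a.id in keep])


def test_demultiplex_exact_prefix(small_library):
    amps = small_library.amplicons
    reads = [amps[0].full_seq, amps[0].full_seq, amps[1].full_seq,
             "TTTTTTTTTT" + amps[0].full_seq]  # shifted barcode -> unassigned
    result = demultiplex(reads, small_library)
    by_id = {b.amplicon_id: b.n_assigned for b in result.bins}
    assert by_id[amps[0].id] == 2 and by_id[amps[1].id] == 1
    assert result.n_unassigned == 1
    assert result.n_assigned + result.n_unassigned == len(reads)


def test_demultiplex_empty(small_library):
    result = demultiplex([], small_library)
    assert result.n_assigned == 0 and result.n_unassigned == 0


def test_align_read_exact_and_mismatch(small_library):
    amp = small_library.amplicons[0]
    hit = align_read(amp.full_seq, amp)
    assert (hit.offset, hit.mismatches) == (0, 0)
    # one substitution accepted, its base recorded in the pileup
    mutated = "A" + amp.full_seq[1:] if amp.full_seq[0] != "A" else \
        "T" + amp.full_seq[1:]
    hit = align_read(mutated, amp)
    assert hit.offset == 0 and hit.mismatches == 1
    # a read that is an interior slice aligns at its true offset
    inner = amp.full_seq[7:30]
    hit = align_read(inner, amp)
    assert hit.offset == 7 and hit.mismatches == 0


def test_align_read_rejects_above_cap(small_library):
    amp = small_library.amplicons[0]
    seq = list(amp.full_seq)
    rng = np.random.default_rng(0)
    for i in rng.choice(len(seq), size=len(seq) // 5, replace=False):
        seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
    assert align_read("".join(seq), amp, max_mismatch_fraction=0.10) is None
    assert align_read(amp.full_seq + "ACGTACGT" * 20, amp) is None  # too long


def test_quantify_by_definition(small_library):
    """90 reference reads + 10 converted reads -> frequency 0.10 at a C site,
    0 at untouched G sites."""
    amp = next(a for a in small_library if a.id == "NNC_ACC")
    c_site = next(s for s in amp.c_sites if s.strand == "+")
    converted = (amp.full_seq[:c_site.position] + "T"
                 + amp.full_seq[c_site.position + 1:])
    bin_ = ReadBin(amp.id, [amp.full_seq] * 90 + [converted] * 10)
    profile = quantify([bin_], small_library, min_depth=10)[0]
    by_pos = {s.position: s for s in profile.sites}
    assert by_pos[c_site.position].frequency == pytest.approx(0.10)
    assert by_pos[c_site.position].converted == 10
    for s in profile.sites:
        if s.position != c_site.position:
            assert s.frequency == 0.0
            assert s.depth == 100


def test_quantify_unknown_amplicon(small_library):
    with pytest.raises(KeyError):
        quantify([ReadBin("nope", [])], small_library)


def test_ct_denominator_option(small_library):
    amp = small_library.amplicons[0]
    site = next(s for s in amp.c_sites if s.strand == "+")
    # a read with an N-like foreign base at the site shrinks the ct denominator
    altered = (amp.full_seq[:site.position] + "G"
               + amp.full_seq[site.position + 1:])
    bin_ = ReadBin(amp.id, [amp.full_seq] * 8 + [altered] * 2)
    depth_prof = quantify([bin_], small_library, min_depth=1)[0]
    ct_prof = quantify([bin_], small_library, min_depth=1,
                       denominator="ct")[0]
    d = {s.position: s for s in depth_prof.sites}[site.position]
    c = {s.position: s for s in ct_prof.sites}[site.position]
    assert d.depth == 10 and c.depth == 8


def test_read_order_invariance(small_library):
    amp = small_library.amplicons[0]
    reads, _ = simulate_library_reads(
        small_library, EditorModel("e", {"AC": 0.2, "CC": 0.2, "GC": 0.2,
                                         "TC": 0.2}),
        depth=300, error_rate=1e-3, seed=9)
    seqs = [s for rid, s in reads if rid.startswith(amp.id + "_")]
    f1 = quantify([ReadBin(amp.id, seqs)], small_library, min_depth=1)[0]
    f2 = quantify([ReadBin(amp.id, seqs[::-1])], small_library, min_depth=1)[0]
    assert [s.frequency for s in f1.sites] == [s.frequency for s in f2.sites]


def test_recovery_at_planted_rates(small_library):
    """Deep simulated reads recover planted rates within the closed-form
    error-inflated expectation +/- 0.01."""
    editor = EditorModel("planted", {"AC": 0.02, "CC": 0.0, "GC": 0.10,
                                     "TC": 0.30})
    error = 1e-3
    reads, truth = simulate_library_reads(small_library, editor, depth=10_000,
                                          error_rate=error, seed=17)
    demux = demultiplex((s for _, s in reads), small_library)
    profiles = quantify(demux, small_library)
    for p in profiles:
        planted = {(t["position"]): t for t in truth.library_rates[p.amplicon_id]}
        for s in p.sites:
            expected = planted[s.position]["expected_frequency"]
            assert s.frequency == pytest.approx(expected, abs=0.01)


def test_call_edited_sites_strict_threshold(small_library):
    amp = small_library.amplicons[0]
    site = next(s for s in amp.c_sites if s.strand == "+")
    def profile_with(freq_num):
        converted = (amp.full_seq[:site.position] + "T"
                     + amp.full_seq[site.position + 1:])
        reads = [amp.full_seq] * (1000 - freq_num) + [converted] * freq_num
        return quantify([ReadBin(amp.id, reads)], small_library)[0]
    assert site.position in {s.position for s in
                             call_edited_sites(profile_with(11))}  # 0.011
    assert site.position not in {s.position for s in
                                 call_edited_sites(profile_with(10))}  # 0.010
    empty = call_edited_sites(profile_with(0))
    assert empty == set()


def test_read_conservation(small_library):
    """assigned + unassigned + alignment-rejected reconciles with input."""
    amp = small_library.amplicons[0]
    garbled = "ACGT" * (len(amp.full_seq) // 4 + 1)
    reads = [amp.full_seq] * 5 + [amp.spacer.barcode +
                                  garbled[:len(amp.full_seq) - 4]] + \
        ["GGGGCCCCAAAA"]
    demux = demultiplex(reads, small_library)
    profiles = quantify(demux, small_library, min_depth=1)
    rejected = sum(p.n_rejected for p in profiles)
    assert demux.n_assigned + demux.n_unassigned == len(reads)
    assert rejected == 1  # the garbled-but-barcoded read
    assert demux.n_unassigned >= 1


def test_pileup_depth_never_exceeds_assigned(small_library):
    amp = small_library.amplicons[0]
    bin_ = ReadBin(amp.id, [amp.full_seq] * 12 + [amp.full_seq[:20]] * 3)
    pile, rejected = pileup_bin(bin_, amp)
    assert rejected == 0
    assert pile.depth.max() <= bin_.n_assigned
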