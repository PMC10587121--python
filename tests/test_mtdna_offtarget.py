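"""Circular-genome off-target calling: recovery of planted sites, SNP masking,
monotonicity, correlations against a rank-formula oracle, motif matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from ddscreen.amplicon_quant import PileupCounts
from ddscreen.mtdna_offtarget import (
    CircularGenome,
    average_offtarget_rate,
    call_otss,
    editing_correlation,
    motif_matrix,
    mt_frequencies,
    ots_overlap,
    read_pileup_tsv,
    snp_mask,
    write_ots_bed,
)
from ddscreen.synthetic_data import simulate_mt_pileup, synthetic_mt_genome


@pytest.fixture(scope="module")
def genome():
    return synthetic_mt_genome(length=16569, seed=21)


@pytest.fixture(scope="module")
def planted(genome):
    """Control/treated pileups with 50 planted OTS and 5 SNPs at depth 5000."""
    cg = [i for i, b in enumerate(genome.sequence) if b in "CG"]
    snps = [(cg[100], 0.98), (cg[900], 0.45), (cg[2000], 0.10),
            (cg[3500], 0.02), (cg[5000], 1.0)]
    control, treated, truth = simulate_mt_pileup(
        genome, n_ots=50, ots_rate_range=(0.05, 0.30), snps=snps,
        depth=5000, error_rate=1e-3, seed=22)
    return control, treated, truth


def test_circular_fetch_matches_doubled_genome_oracle(genome):
    doubled = genome.sequence * 2
    n = len(genome)
    for start, end in [(0, 5), (n - 3, n + 4), (-4, 3), (n - 1, n)]:
        assert genome.fetch(start, end) == doubled[start % n:start % n + (end - start)]
    with pytest.raises(ValueError):
        genome.fetch(0, n + 1)


def test_linear_genome_rejects_wrap():
    g = CircularGenome("lin", "ACGTACGT", circular=False)
    with pytest.raises(IndexError):
        g.fetch(-1, 3)
    assert g.fetch(2, 5) == "GTA"


def test_mt_frequencies_error_free_pileup(genome):
    """A perfect pileup gives frequency 0 everywhere; zero-depth is flagged."""
    L = len(genome)
    counts = np.zeros((L, 5), dtype=np.int64)
    from ddscreen._seq import encode
    idx = encode(genome.sequence)
    counts[np.arange(L), idx] = 100
    counts[7] = 0  # a dropout position
    m = mt_frequencies(PileupCounts(counts), genome)
    finite = np.isfinite(m.frequencies)
    assert np.all(m.frequencies[finite] == 0.0)
    if 7 in m.positions:
        assert not finite[list(m.positions).index(7)]
    with pytest.raises(ValueError):
        mt_frequencies(PileupCounts(counts[:100]), genome)


def test_planted_recovery(genome, planted):
    """>=48 of 50 planted OTS recovered; no SNP site called."""
    control, treated, truth = planted
    cm, tm = mt_frequencies(control, genome), mt_frequencies(treated, genome)
    mask = snp_mask(cm)
    ots = call_otss(tm, mask)
    planted_sites = {(o["position"], o["strand"]) for o in truth.ots}
    snp_sites = {(s["position"], s["strand"]) for s in truth.snps}
    assert len(ots & planted_sites) >= 48
    assert not (ots & snp_sites)
    # per-site rate recovery at a planted OTS
    freqs = tm.frequency_of()
    for o in truth.ots:
        assert freqs[(o["position"], o["strand"])] == pytest.approx(
            o["rate"], abs=0.03)


def test_snp_mask_rules(genome, planted):
    control, _, truth = planted
    cm = mt_frequencies(control, genome)
    mask = snp_mask(cm, threshold=0.01)
    # high-heteroplasmy variants masked; the 1% one sits below the rule
    for s in truth.snps:
        site = (s["position"], s["strand"])
        if s["heteroplasmy"] >= 0.02:
            assert site in mask
    # union rule over multiple controls
    assert snp_mask([cm, cm]) == mask
    clean = np.zeros((len(genome), 5), dtype=np.int64)
    from ddscreen._seq import encode
    clean[np.arange(len(genome)), encode(genome.sequence)] = 50
    assert snp_mask(mt_frequencies(PileupCounts(clean), genome)) == set()


def test_on_target_window_excluded(genome, planted):
    control, treated, truth = planted
    cm, tm = mt_frequencies(control, genome), mt_frequencies(treated, genome)
    mask = snp_mask(cm)
    target = truth.ots[0]
    region = (target["position"] - 5, target["position"] + 6)
    ots = call_otss(tm, mask, on_target_region=region)
    assert (target["position"], target["strand"]) not in ots


def test_masking_and_threshold_monotonicity(genome, planted):
    control, treated, _ = planted
    cm, tm = mt_frequencies(control, genome), mt_frequencies(treated, genome)
    base_mask = snp_mask(cm)
    prev_n = None
    for thr in (0.01, 0.02, 0.05, 0.10):
        n = len(call_otss(tm, base_mask, threshold=thr))
        if prev_n is not None:
            assert n <= prev_n
        prev_n = n
    # enlarging the mask never increases OTS count or the average rate
    bigger = base_mask | set(list(call_otss(tm, base_mask))[:10])
    assert len(call_otss(tm, bigger)) <= len(call_otss(tm, base_mask))
    assert (average_offtarget_rate(tm, bigger)
            <= average_offtarget_rate(tm, base_mask))


def test_average_rate_arithmetic():
    g = CircularGenome("toy", "C" * 1000)
    counts = np.zeros((1000, 5), dtype=np.int64)
    counts[:, 1] = 100  # all C
    counts[0, 1], counts[0, 3] = 90, 10  # one site at 0.10
    m = mt_frequencies(PileupCounts(counts), g)
    assert average_offtarget_rate(m, set()) == pytest.approx(1e-4)
    allzero = counts.copy()
    allzero[0] = 0
    allzero[0, 1] = 100
    m0 = mt_frequencies(PileupCounts(allzero), g)
    assert average_offtarget_rate(m0, set()) == 0.0


def test_ots_overlap_reports():
    a = {(1, "+"), (2, "+"), (3, "-")}
    b = {(2, "+"), (3, "-"), (4, "+")}
    rep = ots_overlap(a, b)
    assert (rep.n_a, rep.n_b, rep.n_shared) == (3, 3, 2)
    assert rep.coverage_b == pytest.approx(2 / 3)
    same = ots_overlap(a, a)
    assert same.coverage_a == same.coverage_b == 1.0
    assert ots_overlap(a, set()).n_shared == 0


def _map_from(genome, site_freqs):
    m = mt_frequencies(_uniform_pileup(genome), genome)
    f = m.frequencies.copy()
    lookup = {s: i for i, s in enumerate(m.sites)}
    for site, freq in site_freqs.items():
        f[lookup[site]] = freq
    m.frequencies = f
    return m


def _uniform_pileup(genome):
    from ddscreen._seq import encode
    L = len(genome)
    counts = np.zeros((L, 5), dtype=np.int64)
    counts[np.arange(L), encode(genome.sequence)] = 100
    return PileupCounts(counts)


def test_spearman_matches_rank_formula_oracle():
    g = CircularGenome("toy", "ACGTACGTACGTACGTACGT")
    sites = [(i, "+" if g.sequence[i] == "C" else "-")
             for i in range(len(g)) if g.sequence[i] in "CG"][:4]
    fa = dict(zip(sites, [0.02, 0.08, 0.03, 0.11]))
    fb = dict(zip(sites, [0.03, 0.06, 0.09, 0.12]))  # one discordant pair
    ma, mb = _map_from(g, fa), _map_from(g, fb)
    res = editing_correlation([ma, mb], ots_sets=[set(sites), set(sites)],
                              labels=["a", "b"])
    xa = [fa[s] for s in sorted(sites)]
    xb = [fb[s] for s in sorted(sites)]
    ra, rb = rankdata(xa), rankdata(xb)
    oracle = np.corrcoef(ra, rb)[0, 1]
    assert res.matrix.loc["a", "b"] == pytest.approx(oracle)
    assert res.matrix.loc["a", "a"] == 1.0


def test_spearman_rank_invariance_and_clustering(genome, planted):
    control, treated, _ = planted
    tm = mt_frequencies(treated, genome)
    monotone = mt_frequencies(treated, genome)
    monotone.frequencies = np.sqrt(monotone.frequencies)  # rank-preserving
    cm = mt_frequencies(control, genome)
    mask = snp_mask(cm)
    res = editing_correlation([tm, monotone, cm], mask=mask,
                              labels=["t", "t_sqrt", "ctrl"])
    assert res.matrix.loc["t", "t_sqrt"] == pytest.approx(1.0)
    assert res.matrix.equals(res.matrix.T)
    # average-linkage order puts the two rank-identical samples together
    order = res.leaf_order
    assert abs(order.index("t") - order.index("t_sqrt")) == 1
    with pytest.raises(ValueError):
        editing_correlation([tm])


def test_motif_matrix_tc_planted(genome):
    """OTS planted exclusively at TC sites give T probability 1.0 at -1."""
    _, treated, truth = simulate_mt_pileup(
        genome, n_ots=30, ots_rate_range=(0.05, 0.2), depth=3000,
        error_rate=0.0, seed=30, ots_context="TC")
    ots = {(o["position"], o["strand"]) for o in truth.ots}
    assert len(ots) == 30
    mat = motif_matrix(ots, genome)
    assert mat.loc[0, "C"] == 1.0
    assert mat.loc[-1, "T"] == 1.0
    assert np.allclose(mat.sum(axis=1), 1.0)
    with pytest.raises(ValueError):
        motif_matrix(set(), genome)


def test_motif_matrix_single_site_and_wraparound():
    g = CircularGenome("toy", "CTTTTTAAAAA")  # C at origin, flanks wrap
    mat = motif_matrix({(0, "+")}, g)
    assert mat.loc[0, "C"] == 1.0
    assert mat.loc[-1, "A"] == 1.0  # 5' neighbour wraps to the genome end
    assert mat.loc[1, "T"] == 1.0


def test_pileup_tsv_and_bed_round_trip(tmp_path, genome, planted):
    _, treated, _ = planted
    path = tmp_path / "pileup.tsv"
    treated.to_frame().to_csv(path, sep="\t", index=False)
    again = read_pileup_tsv(path)
    assert np.array_equal(again.counts, treated.counts)
    tm = mt_frequencies(treated, genome)
    ots = call_otss(tm, set())
    bed = tmp_path / "ots.bed"
    write_ots_bed(ots, tm.frequency_of(), genome.name, bed)
    df = pd.read_csv(bed, sep="\t", header=None)
    assert len(df) == len(ots)
    assert ((df[2] - df[1]) == 1).all()
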