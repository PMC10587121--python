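# Methods

## The screening problem

Double-stranded-DNA cytidine deaminases (DddA and its homologs), split in
half and fused to TALE arrays, form base editors (DdCBEs) that convert C·G
to T·A inside the spacer between the two TALE binding sites. Editors differ
in which NC dinucleotide context (the base 5' of the edited C: AC, CC, GC,
TC) they accept, how strongly they edit at each position of the spacer, and
how much off-target deamination their spontaneously assembled halves cause.
This package implements the computational machinery of a saturated
spacer-library screen that characterizes all of these properties in one
amplicon-sequencing experiment, plus the surrounding analyses: homolog
mining, whole-mtDNA off-target profiling, inhibitor quantification,
editing-window optimization, and nuclear off-target candidate prediction.

## Library design

A spacer is six tandem copies of one C-containing triplet. Triplets are
partitioned by the position of a fixed C, with earlier subsets claiming
shared triplets (NNC → NCN → CNN):

* NNC: C at triplet position 3 — 16 combinations minus CCC = 15;
* NCN: C at position 2, position 3 ≠ C — 12;
* CNN: C at position 1 only — 9.

The union is exactly the 36 C-containing triplets other than CCC (CCC is
excluded because homopolymeric C runs are error-prone in amplification and
sequencing), so six-fold repetition saturates every NC context at multiple
spacer offsets. Two locus-derived control spacers complete a 38-member
library. Each amplicon is `barcode + left TALE site + spacer + right TALE
site`; the 4-nt barcode drives exact-prefix demultiplexing. Barcode
sequences are generated pseudo-randomly (seed-deterministic, distinct, and
never equal to the left TALE prefix) because the physical barcode sequences
are interchangeable for the analysis; the bundled JAK2/SIRT6-analogue
spacers and default TALE sites are synthetic stand-ins, labelled as such in
the source.

Every C (plus strand) and G (a C on the minus strand) inside the spacer is
annotated with its strand and 5'-adjacent base *on the edited strand* — for
a reference G the context is the complement of the base 3' of the G.
Coordinates are 0-based half-open throughout.

Candidate editors are enumerated as protein × split site × orientation
(NC/CN); the default 2 × 2 gives four editor pairs per protein. The
editing-window suite slides a fixed-length window across a core sequence so
that one target C/G sits at n distinct distances from the fixed TALE site.

## Homolog mining

Candidates are filtered for the two zinc-coordinating motifs required for
deaminase activity: the literal tripeptide HVE and a CxxC cysteine pair
(all, possibly overlapping, occurrences are reported). Redundancy removal is
CD-HIT-style greedy incremental clustering: records sorted by length
descending (ties by id); each joins the first cluster whose representative
it matches at ≥ threshold identity, else founds a cluster. Identity is
global-alignment identity — matched columns / all alignment columns, match
1, mismatch 0, linear gap penalty −1 (Biopython `PairwiseAligner`). This is
exact rather than CD-HIT's k-mer heuristic; the two can disagree only for
pairs near the threshold. Defaults: redundancy removal at 0.90 (the
conventional default for protein redundancy removal), representative
selection at 0.80. Representative selection is global rather than
per-clade: clades are themselves identity-driven, so a global 80% pass
approximates clade-wise selection without requiring a tree.

## Editing quantification

Reads are assigned by exact barcode prefix match; unassigned reads are
counted. Placement on the amplicon is gapless: best offset by minimum
mismatches, rejected above a mismatch cap (default 10%). Amplicons are
short and fixed-structure, so substitution-only placement suffices;
indel-bearing reads are rejected and counted, which mirrors the effect of
strict mapping with a general-purpose aligner but is a deliberate
simplification of it. Full-length reads (the overwhelming case) are checked
at offset 0 in one vectorized pass.

Conversion frequency at a site is `T / depth` for a plus-strand C and
`A / depth` for a reference G, with depth the total non-N count at that
position. Published pipelines are ambiguous about the denominator, so a
reference+converted-only variant (`denominator="ct"`) is provided. Sites
below `min_depth` (default 100) are flagged, not dropped. An edited site is
one with frequency *strictly* greater than the threshold (default 0.01,
i.e. the ">1%" rule).

With conversion rate r and uniform error rate e, the expected observed
frequency is `r(1−e) + (1−r)e/3`; recovery tests assert against this closed
form within binomial confidence bounds.

## Context statistics

Per NC context: `n_edited` (sites above threshold), `max_edit`, `mean_edit`
over *all* sites of the context (edited or not), and `proportion` =
context's share of edited sites. Proportions are count-weighted (each edited
site counts once); an efficiency-weighted variant is behind a flag, since
either convention is defensible. A C 5' of another C is counted in CC
independently of whether both are edited — context is a property of the
reference sequence.

Inhibitor effect is `log2((f_with + p)/(f_without + p))` per site, restricted
to sites edited without inhibitor; the pseudocount p (default 1e-4) bounds
the ratio when a frequency is zero and preserves rank order.

Window scores: on-target frequency, bystander aggregate = *sum* of
frequencies at all other C/G sites in the window (sum penalizes multi-site
bystander editing; a max variant is available), and their pseudocounted
ratio. Windows are ranked by ratio then on-target frequency; windows with
on-target frequency below 1% are flagged inactive.

## Whole-mtDNA off-target analysis

The genome is circular: flank extraction wraps the origin (verified against
a doubled-genome oracle). From a per-position pileup, every reference C/G
gets a conversion frequency; zero-depth sites are flagged and excluded from
averages. SNP masking follows the ">1% in control" rule with a union over
multiple controls; a precomputed SNP list can replace control-derived
masking. OTS are unmasked, off-window sites above 1%. The average
off-target rate is the mean over all unmasked, covered C/G sites (not just
OTS) — the all-site denominator makes editors with few but strong OTS
comparable to editors with many weak ones; an OTS-only mean is exposed as an
option. Sample comparison uses Spearman correlation over the union of OTS
called in any sample (an all-sites variant exists), clustered by average
linkage on 1 − ρ. Motif matrices take ±5 nt flanks around each OTS,
reverse-complementing minus-strand sites so the edited base reads C at the
center, and report per-position base probabilities. Reports use 1-based
"m." positions; internals stay 0-based.

## Nuclear off-target prediction

A candidate locus is a placement of the left and right TALE sites, each
within a per-site Hamming mismatch cap (default 20%), separated by a spacer
in the configured range (on-target length ± 4 by default), right site
downstream of the left on the same strand. Both strands are scanned (minus
strand via the reverse complement, reported in plus-strand coordinates).
Substitution-only matching with a deterministic cap replaces a
local-alignment search: the loci of interest are near-duplicates of the
target arrangement, for which Hamming distance is the right neighbourhood,
and the matcher is provably equivalent to an exhaustive sliding-window scan
(tested against one). Indel-containing homologies are not found — a known
limitation. 500 bp flanks (clipped at contig ends) are exported for primer
design, which is out of scope.

## Synthetic data

The generator encodes the study conditions the analyses expect:

* **Library reads** — per amplicon, `depth` reads (default 5,000, matching
  the >5,000× coverage regime the screen operates in); each annotated site
  converts independently at rate `context_weight × window_weight ×
  strand_factor`; uniform substitution error (default 1e-3, typical of
  high-accuracy short-read data) applied after editing, uniformly over the
  three alternate bases; constant Phred qualities, since quantification
  ignores them.
* **mtDNA pileups** — a random circular genome of mtDNA length (16,569 bp)
  and GC fraction 0.44; 50 off-target sites at rates 0.05–0.30 by default,
  sampled without replacement from C/G sites (optionally restricted to one
  NC context); SNPs at specified heteroplasmy present in control and
  treated pileups alike; per-position multinomial counts at depth 5,000.
  Infeasible context requests record a shortfall rather than failing.
* **Homolog sets** — motif-positive families (point-mutated copies of a
  founder, motifs protected) plus motif-negative decoys, with family labels
  as ground truth.

Editor presets (`tc_canonical`, `gc_editor`, `ac_editor`, `null`) mimic the
qualitative preference classes of characterized deaminases; their rate
values are invented. Everything is seed-deterministic; identical seeds give
byte-identical FASTQ output.

What the simulations do *not* model: strand- or context-specific sequencing
error, homopolymer artifacts, PCR duplication, indels, coverage
non-uniformity, and NUMT contamination. Passing recovery tests therefore
demonstrates correctness of the quantification and calling logic under the
stated noise model, not robustness to every artifact of real libraries.

## Numerical and design choices

* Threshold comparisons for edited-site and OTS calls are strict (>), so a
  frequency exactly at threshold is negative.
* Frequencies at zero-depth sites are NaN and flagged; they never enter
  means or correlations.
* Tie-breaks: alignment offsets prefer the smallest; clustering order is
  length-descending then id; nuclear hits sort by total mismatches then
  coordinate; window ranking by ratio then on-target frequency.
* Problem sizes in the test and acceptance runs (depth 10,000 over the
  36-amplicon library for recovery; one 16.6 kb genome at depth 5,000 for
  off-target recovery; 10 kb contigs for the matcher-oracle equivalence)
  were chosen as the smallest sizes at which binomial uncertainty is well
  inside the assertions' tolerances.

## Known limitations

* Pairwise identity is exact global alignment, O(nm) per pair; clustering
  thousands of proteins is quadratic in the worst case. Fine for hundreds
  of candidates, slow for proteome-scale input.
* Gapless read placement discards indel-bearing reads instead of
  realigning them.
* The nuclear matcher does not model indels or scoring-matrix homology.
* Paired-end merging, trimming and QC are assumed done upstream.
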