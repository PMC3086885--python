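# Methods

This note documents the models behind each stage, the tunable parameters
with their defaults and rationale, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
genuinely open. No empirical claim here goes beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Homology search and E-values

Local alignment is affine-gap Smith–Waterman (match +1, mismatch −3, gap
open 5, gap extend 2 — classic nucleotide-BLAST-like defaults), executed
by Biopython's `PairwiseAligner`; `N` scores as a mismatch against
everything, so masked positions can never anchor an alignment. Hairpins
are always the plus-strand query and every subject is searched on both
strands.

Significance uses ungapped Karlin–Altschul statistics,
E = K·m·n·e^(−λS), with λ solved numerically from
Σ pᵢpⱼ·e^(λ·sᵢⱼ) = 1 at uniform background (λ ≈ 1.374 for +1/−3) and K
taken from the standard ungapped table for common match/mismatch pairs
(fallback 0.35). Search-space sizes m, n are the raw sequence lengths —
no edge-effect correction. Applying ungapped statistics to gapped
alignments and skipping the edge correction both bias E slightly, in
opposite directions; the null-calibration test bounds the consequence
(observed HSP counts at E ≤ t stay within ~3·t per subject).

Multiple HSPs per sequence pair come from iterative masking of the
*query* interval of each accepted HSP. Masking the query rather than the
subject lets the two arms of one hairpin hit the same repeat consensus on
opposite strands — the signature of a hairpin assembled from two inverted
cognate copies — at the cost of missing a second subject site aligning to
an already-used query region, which does not arise in these screens.

Thresholds: TE-MIR call at E ≤ 0.005; target HSPs kept at E ≤ 0.05 with
genes kept at E ≤ 0.01. Genes described as hypothetical proteins are
excluded from the initial-target set (their HSPs remain in the table).
Annotation classing is a configurable keyword rule (transposon,
retrotransposase, MULE, hAT, CACTA, helitron, MITE, gypsy, copia, … →
TE-related; "expressed protein"/"unknown" → expressed-unknown; otherwise
non-TE), matched on word boundaries.

## Folding and the duplex call

The fold maximises summed pair weights (GC = 3, AU = 2, GU = 1, minimum
loop 3) with an O(n³) Nussinov kernel (numba-jitted, pure-Python
fallback). Only stem geometry is consumed downstream — which positions
pair, and where the arms are — so a full thermodynamic model would add
accuracy nothing uses while making the component untestable against
enumeration; an external folder can be substituted by constructing
`HairpinStructure` directly. The main stem is the longest chain of
strictly nested pairs; its outer and inner pairs delimit the 5′ and 3′
arms.

The duplex call takes the most abundant plus-strand read as the miR
candidate, locates its pairing-partner interval through the pair table,
and accepts miR\* support from any non-overlapping plus-strand read whose
placement leaves ~2-nt 3′ overhangs at both duplex ends (tolerance ±1 nt;
Dicer-offset tolerance is not standardised anywhere, so ±1 is the
operational choice). When a position at a window edge is unpaired (a
duplex mismatch), the nearest paired neighbour within 2 nt extrapolates
the partner. A call is *precise* when (a) the dominance ratio — top read
abundance over the largest other read overlapping its window, floor 1 —
reaches 5, (b) the miR + miR\* windows (±3 nt slop) hold ≥ 75 % of total
plus-strand abundance, and (c) the overhang geometry holds. The
dominance and concentration cutoffs quantify "one major species plus
weakly expressed variants" and "reads concentrated in specific regions";
both are exposed parameters, echoed in report headers.

The typical screen is the conjunction: mean genome hits ≤ 20, strand
category in {plus only, plus major}, precise excision. The minority
strand is "negligible" at ≤ 10 % of total abundance (`minor_fraction`);
no published number exists for this, so it is configurable. Length types
use dominance > 50 % per usable dataset (total ≥ 10), with 20–22 nt
counting toward "21 major" and 23–24 nt toward "24 major".

Architecture calls fold the hairpin core (flanks join the alignment query
but not the fold — folding hundreds of random flanking bases would bury
the arms): one HSP covering ≥ 60 % of the two-arm span ⇒ single
palindrome; else two non-overlapping opposite-strand HSPs to one family,
each covering ≥ 60 % of one arm ⇒ inverted pair; else neither. The
single-palindrome test runs first because a palindromic element also
produces arm-wise minus-strand self-HSPs.

## Target prediction

Pairing scores follow the plant (TargetFinder/Allen-style) convention:
mismatch 1, G:U 0.5, bulge on either strand 2, all penalties doubled at
sRNA positions 2–13 from the 5′ end. The alignment is a bounded-gap DP
(≤ 1 bulge per strand) of the full sRNA against candidate windows; with
one bulge per strand the window length can differ from the sRNA by at
most 1, so windows of |sRNA| ± 1 are enumerated. A vectorised ungapped
prescreen (same penalties, no gaps) limits the DP to windows within
score_max + 6 — far above anything a single bulge (cost ≥ 2) could
rescue — so the prescreen is a pure speed optimisation and every
qualifying site reaches the DP.

The duplex energy proxy sums nearest-neighbour stack terms
(Watson–Crick + G:U stacks, Turner-like magnitudes; terminal penalties
and loop terms ignored) over consecutive paired positions; mismatches
and bulges break the helix. Because the MFE ratio divides this by the
same proxy evaluated on the perfect complement, systematic offsets in
the table largely cancel; absolute kcal/mol accuracy is explicitly not
claimed. A perfect complement gives ratio 100 exactly. Predictions are
kept at score ≤ 4 and ratio ≥ 73 %; by default only sRNAs from the plus
strand of their hairpin participate. An HSP is an MTPH when at least one
sRNA of that TE-MIR has a kept prediction on that gene.

## Degradome scoring

Tags (≥ 15 nt) map exactly to the cDNA plus strand; the 5′ end defines
the counted position. The predicted cleavage position is the cDNA
coordinate paired to sRNA position 10; if a bulge swallows position 10
the call is refused. Categories over the transcript profile: 1 = the
site ties the maximum over expressed positions (no uniqueness demanded —
it is the strongest evidence class and a tie does not weaken it);
2 = above the median of expressed positions (median over positions with
≥ 1 tag only) but below the maximum; 3 = expressed otherwise. A profile
with a single expressed position makes that position category 1.
Categories detected across all qualifying site predictions (pairing
score ≤ 4) union per target; the summary score adds 4/2/1 for categories
1/2/3, reproducing the printed seven-case table, with 0 for no evidence.
Datasets never mix.

## The synthetic world

The generator states one world and the tests measure against it:

- **Background**: i.i.d. uniform A/C/G/T. No isochore or composition
  model — downstream the only thing that matters is that non-homologous
  sequence stays non-homologous.
- **TE families**: a consensus (palindromic termini of `tir_len` ≥ 10 nt
  for MITEs) and copies mutated by uniform substitutions at a stated
  divergence. No indels, no nested insertions, no age structure.
- **Hairpin loci**: either a single palindromic element or two cognate
  copies head-to-head around a 5–50 nt spacer. Copies destined to be
  hairpin loci are *speciated*: stem substitutions are compensatory
  (the mirrored position co-mutates), loop substitutions free, and 2
  non-compensatory substitutions are planted inside the miR/miR\*
  pairing span plus 2 elsewhere. This mirrors real precursor evolution
  (structure conserved, arms imperfectly complementary) and is also what
  makes exact mapping meaningful: a perfectly palindromic locus would
  put every plus-strand read on both strands, as real perfect
  inverted repeats do.
- **sRNA reads**: per dataset an independent multinomial resample of a
  shared pool at the stated depth. Precise mode concentrates
  `concentration` (default 0.85) of each window's weight on the dominant
  read with geometrically decaying shifted variants (the miR window takes
  0.7 of plus-strand weight, the miR\* window 0.3); smeared mode spreads
  uniform windows along the locus with lengths allocated to the stated
  spectrum by largest remainder. Strand categories are realised as
  minority-strand pool fractions (0 / 0.05 / 0.5 / 0.95 / 1); the pool
  split is exact so a planted category is recovered up to multinomial
  noise only. No sequencing-error model; the abundance-ratio separating
  a "major species" from variants is a parameter, not a fitted value.
- **Initial targets**: a cognate copy is written across the CDS start
  (antisense by default, with enough of the element inside the CDS that
  the reverse complement of the miR window lands in coding sequence) and
  flagged `te_overlaps_cds_boundary`. Fully-internal insertion is
  available but is not the boundary-spanning situation the flag records.
- **Degradome**: a planted peak at the predicted slicing position plus
  bounded background noise (noise positions drawn without replacement,
  each carrying exactly the stated noise count, which keeps tie
  constructions deterministic).

A green synthetic test therefore establishes that each operation recovers
what the generator planted under exact-match mapping and the stated noise
models — not that the thresholds are optimal for real rice data, where
divergence structure, multi-mapping and sequencing artefacts are richer.

## Determinism and output

Every stochastic operation takes a seed and derives per-locus seeds
deterministically; pipeline reruns with one seed are byte-identical, so
report files carry no timestamps (timing goes to the log stream). Report
tables echo every threshold in their header line; coordinates are
0-based half-open in memory, GFF3 is written 1-based inclusive, and
prediction tables print 1-based inclusive site coordinates.

## Known limitations

- Ungapped E-value statistics over gapped alignments; no composition
  adjustment.
- The Nussinov fold has no thermodynamics; co-optimal structures are
  resolved by traceback order, which can shift partner positions by a few
  nucleotides near mismatch clusters (the duplex caller tolerates ±1 nt
  overhang error and ±2 nt partner search for exactly this reason).
- Query-side HSP masking can hide a second subject site that reuses an
  already-aligned query region.
- The duplex-energy table is a proxy; only ratios are meaningful.
- Exact-match read mapping means any sequencing error or SNP drops a
  read, as in the original mismatch-free design.
- Multi-mapping reads are neither apportioned nor discarded; genome
  multiplicity averages over unique read sequences, unweighted by
  abundance, excluding zero-hit reads (counted separately).
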