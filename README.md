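# temir

Analysis pipeline for **transposable-element-derived plant miRNA genes
(TE-MIRs)**: identifying annotated miRNA stem-loops with significant
homology to TEs and repeats, screening them against plant miRNA annotation
criteria, discovering the protein-coding "initial target" genes created by
cognate TE insertion into coding sequence, and validating targeting with
degradome (PARE) cleavage evidence summarised by a 1–7 score.

It is written for small-RNA and regulatory-genomics researchers who want a
tested, reusable, fully synthetic-testable version of this analysis: every
input (TE library, genome with annotation, sRNA read sets, degradome tag
sets) can be generated with known ground truth, so each stage is verifiable
without downloading any public database.

## What it computes

Given miRNA stem-loop sequences, a repeat/TE library with class labels, a
genome with gene annotation and CDS/cDNA sets, sRNA read sets and degradome
5′-tag sets:

1. **TE-MIR identification** — Smith–Waterman local alignment of each
   hairpin against the repeat library with Karlin–Altschul statistics,
   E = K·m·n·e^(−λS). A hairpin is a TE-MIR when at least one HSP reaches
   **E ≤ 0.005**; it inherits the class (MITE / retrotransposon / other DNA
   transposon) of its best-E subject.
2. **sRNA expression profiling** — exact (mismatch-free) mapping of reads
   to hairpins and genome on both strands; per-hairpin strand-bias category
   (*plus only / minus only / plus major / minus major / both*), unweighted
   mean genome hit count, and length-distribution type (*low / 21 major /
   24 major / mixed / other*, judged per dataset with a usable-total
   threshold of 10). Abundances normalise to transcripts per quarter
   million (TPQ = count·250000/total).
3. **miRNA annotation screen** — weighted Nussinov folding (GC=3, AU=2,
   GU=1, loop ≥ 3) locates the stem; a hairpin is a *typical* (bona fide)
   TE-MIR iff its sRNAs have mean genome hit **≤ 20**, come purely or
   predominantly from the plus strand, and document precise excision of an
   miRNA/miRNA\* duplex with ~2-nt 3′ overhangs. Locus architecture is
   called as a single palindromic element or two juxtaposed inverted
   cognate copies.
4. **Initial-target discovery** — hairpins vs CDS at **E ≤ 0.05** per HSP,
   genes kept at **E ≤ 0.01** (hypothetical proteins removed), classed as
   TE-related / non-TE / expressed-unknown by annotation keywords.
5. **Target prediction** — plant-style complementarity scoring (mismatch 1,
   G:U 0.5, bulge 2; penalties doubled at sRNA positions 2–13) with a
   nearest-neighbour duplex-energy ratio; pairs kept at **score ≤ 4** and
   **MFE ratio ≥ 73 %**. HSPs whose gene is also a predicted target of the
   homologous TE-MIR are MTPHs (MIR–target-pair HSPs).
6. **Degradome validation** — 5′ tags mapped exactly onto target cDNAs;
   the count at the position opposite sRNA nucleotide 10 is classified as
   category 1 (ties the transcript maximum), 2 (above the median of
   expressed positions) or 3 (expressed, at or below the median); detected
   categories union into a per-target score: {1,2,3}→7, {1,2}→6, {1,3}→5,
   {1}→4, {2,3}→3, {2}→2, {3}→1.

## Worked example

Run the full pipeline on its default synthetic world (12 hairpin loci —
3 planted typical, 7 planted atypical, 2 random decoys — 8 genes, 3 of
which carry boundary-spanning cognate TE insertions):

```bash
temir run --seed 1 --out demo
```

`demo/report/typical_table.tsv` (the machine version of a per-hairpin
annotation table):

```
hairpin_id  strand_category  mean_genome_hits  length_type  ...  verdict   architecture
temir0      plus_only        2.0               major21      ...  typical   single_palindrome
temir1      plus_major       2.0               major21      ...  typical   single_palindrome
temir2      plus_only        2.0               major21      ...  typical   inverted_pair
temir3      plus_major       1.08              major24      ...  atypical  single_palindrome
```

All three planted typical loci pass the screen (low genome multiplicity,
plus-strand bias, precise duplex excision), including the one assembled
from two inverted retrotransposon copies; smeared, high-copy and
both-strand loci are rejected. `te_class_freq.tsv` shows the repeat-class
breakdown of the 10 TE-MIR calls (7 MITE, 2 other DNA, 1 retrotransposon;
the 2 decoys are not called). `cleavage_scores.tsv` holds the degradome
summary per target and dataset:

```
gene_id  dataset_id  categories  score
gene0    deg0        1,3         5
gene1    deg0        1,3         5
gene2    deg0        1           4
```

Score 5 means cleavage evidence of categories 1 and 3 was detected; score 4
means category 1 only — the planted cleavage peak opposite sRNA position 10
was recovered as the transcript maximum in every case. `summary.json`
echoes every threshold and per-stage record count (10 TE-MIRs, 3 typical,
3 initial targets, 3 MTPHs for this seed).

## Acceptance script

`scripts/acceptance.py` recomputes the per-target summary cleavage scores
from scratch: for each category combination it synthesises a transcript,
predicts the sRNA–target pairings, maps generated degradome tags,
classifies the evidence at each predicted slicing position and reports the
resulting summary score.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Library and CLI

Every stage is a plain function (`temir.homology.find_te_mirs`,
`temir.profiling.build_profile`, `temir.annotation.screen_typical`,
`temir.targets.predict_targets`, `temir.degradome.score_targets`,
`temir.synthetic.*`); the `temir` command exposes thin wrappers
(`simulate`, `homology`, `profile`, `annotate`, `targets`, `predict`,
`degradome`, `run`) over the same plain-text formats (FASTA, TSV, GFF3,
JSON). See `docs/methods.md` for the models, parameter choices and known
limitations.
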