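"""Synthetic TE / genome / small-RNA / degradome generator with ground truth.

Every downstream stage of the pipeline is tested against worlds produced
here: TE families with palindromic (MITE-like) and non-palindromic
members at controlled genomic copy number; hairpin loci formed either by
a single palindromic element or by two adjacent inverted cognate copies
separated by a short spacer; protein-coding genes whose CDS partially
overlaps a cognate TE insertion across a coding/non-coding boundary;
small-RNA read populations with controlled strand bias, length spectrum
and excision precision; and degradome tag profiles with a planted
cleavage peak plus background noise.

Background sequence is i.i.d. uniform A/C/G/T — homology-search
specificity downstream is what matters, not base composition realism.
All operations are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequtil import random_seq, revcomp

TE_CLASSES = ("MITE", "retrotransposon", "other_DNA", "unclassified")

STRAND_CATEGORIES = ("plus_only", "minus_only", "plus_major", "minus_major", "both")

#: minority-strand abundance fraction used to realise each planted category
_MINOR_FRACTION = {
    "plus_only": 0.0,
    "plus_major": 0.05,
    "both": 0.5,
    "minus_major": 0.95,
    "minus_only": 1.0,
}


# ---------------------------------------------------------------------------
# TE families


@dataclass
class TeFamily:
    """A TE family: consensus plus mutated genomic copies.

    ``tir_len`` is the terminal-inverted-repeat length (0 for elements
    without TIRs); a MITE consensus is palindromic at its termini, i.e.
    its first ``tir_len`` nt are the reverse complement of its last
    ``tir_len`` nt.
    """

    family_id: str
    te_class: str
    consensus: str
    tir_len: int
    copies: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"invalid TE class {self.te_class!r}")
        if self.te_class == "MITE":
            t = self.tir_len
            if t < 10:
                raise ValueError("MITE requires tir_len >= 10")
            if self.consensus[:t] != revcomp(self.consensus[-t:]):
                raise ValueError("MITE consensus termini are not reverse-complementary")


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitutions placed uniformly at the given per-site rate."""
    if divergence == 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < divergence)[0]
    for i in hits:
        alternatives = [c for c in "ACGT" if c != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def generate_te_family(te_class: str, length: int, tir_len: int, n_copies: int,
                       divergence: float, seed: int,
                       family_id: str | None = None) -> TeFamily:
    """Build a consensus and ``n_copies`` mutated copies of it.

    MITE consensuses get reverse-complementary termini of ``tir_len`` nt;
    other classes ignore ``tir_len`` unless explicitly requested.
    """
    if te_class not in TE_CLASSES:
        raise ValueError(f"invalid TE class {te_class!r}")
    if not 0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    if length < 2 * tir_len + 20:
        raise ValueError("tir_len too large for length")
    rng = np.random.default_rng(seed)
    if te_class == "MITE" and tir_len < 10:
        raise ValueError("MITE requires tir_len >= 10")
    if tir_len > 0:
        tir = random_seq(tir_len, rng)
        core = random_seq(length - 2 * tir_len, rng)
        consensus = tir + core + revcomp(tir)
    else:
        consensus = random_seq(length, rng)
    copies = [(_mutate(consensus, divergence, rng), divergence) for _ in range(n_copies)]
    fid = family_id or f"{te_class}_fam{seed}"
    return TeFamily(family_id=fid, te_class=te_class, consensus=consensus,
                    tir_len=tir_len, copies=copies)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def speciate_hairpin_copy(family: TeFamily, mir_window: tuple[int, int], seed: int,
                          divergence: float = 0.10,
                          n_duplex_mismatches: int = 2,
                          n_other_mismatches: int = 2) -> str:
    """A hairpin-locus copy: diverged from the family consensus but with a
    preserved stem.

    Emulates sequence speciation of a TE-derived hairpin under selection
    for structure: substitutions inside the terminal-inverted-repeat stem
    are compensatory (the mirrored position co-mutates to keep the pair),
    loop substitutions are free, and a small number of non-compensatory
    substitutions are planted as internal duplex mismatches — at least
    ``n_duplex_mismatches`` of them inside the miR/miR* pairing span, as
    in real plant miRNA duplexes.  Those duplex mismatches also break the
    exact minus-strand self-match of the miR and miR* reads, so a
    plus-strand-only read population stays plus-only under exact mapping.
    """
    rng = np.random.default_rng(seed)
    seq = list(family.consensus)
    L = len(seq)
    t = family.tir_len
    if t < 20:
        raise ValueError("hairpin speciation needs a long terminal inverted repeat")
    s, e = mir_window
    if not (0 <= s < e <= t or L - t <= s < e <= L):
        raise ValueError("miR window must sit inside one stem arm")

    def co_mutate(i: int) -> None:
        j = L - 1 - i
        alternatives = [c for c in "ACGT" if c != seq[i]]
        seq[i] = alternatives[rng.integers(3)]
        seq[j] = _COMP[seq[i]]

    # compensatory stem + free loop divergence
    for i in range(t):
        if rng.random() < divergence:
            co_mutate(i)
    for i in range(t, L - t):
        if rng.random() < divergence:
            alternatives = [c for c in "ACGT" if c != seq[i]]
            seq[i] = alternatives[rng.integers(3)]

    # mirror of the miR window on the 5' arm (pair columns are symmetric)
    ws, we = (s, e) if e <= t else (L - e, L - s)
    interior = np.arange(ws + 3, we - 4)
    for i in rng.choice(interior, size=min(n_duplex_mismatches, len(interior)), replace=False):
        cur = seq[i]
        choices = [c for c in "ACGT" if c != cur and _COMP[c] != seq[L - 1 - i]]
        seq[int(i)] = choices[rng.integers(len(choices))]
    outside = np.array([i for i in range(t) if i < ws - 2 or i >= we + 2])
    if len(outside) and n_other_mismatches:
        for i in rng.choice(outside, size=min(n_other_mismatches, len(outside)), replace=False):
            cur = seq[int(i)]
            choices = [c for c in "ACGT" if c != cur and _COMP[c] != seq[L - 1 - int(i)]]
            seq[int(i)] = choices[rng.integers(len(choices))]
    return "".join(seq)


def plant_duplex_mismatches(copy_seq: str, mir_window: tuple[int, int], seed: int,
                            n_inside: int = 2, n_outside: int = 2) -> str:
    """Mutate a cognate copy so a juxtaposed-inverted-pair stem holds
    internal mismatches.

    For a locus built as copy1 + spacer + revcomp(copy2), stem position i
    pairs copy1[i] with the complement of copy2[i]; substituting copy2 at
    a position therefore opens a duplex mismatch there.  At least
    ``n_inside`` substitutions land inside the miR pairing span (breaking
    the exact minus-strand self-match of the miR/miR* reads) and
    ``n_outside`` elsewhere.
    """
    rng = np.random.default_rng(seed)
    seq = list(copy_seq)
    s, e = mir_window
    interior = np.arange(s + 3, e - 4)
    outside = np.array([i for i in range(len(seq)) if i < s - 2 or i >= e + 2])
    for pool, n in ((interior, n_inside), (outside, n_outside)):
        if not len(pool) or n == 0:
            continue
        for i in rng.choice(pool, size=min(n, len(pool)), replace=False):
            cur = seq[int(i)]
            alternatives = [c for c in "ACGT" if c != cur]
            seq[int(i)] = alternatives[rng.integers(3)]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Genome truth


@dataclass
class Insertion:
    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # the copy in its own orientation


@dataclass
class HairpinLocus:
    locus_id: str
    architecture: str  # single_palindrome | inverted_pair
    chrom: str
    start: int
    end: int
    family_id: str


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: tuple[int, int]
    description: str
    te_overlaps_cds_boundary: bool = False


@dataclass
class GenomeTruth:
    genome: dict[str, str]
    insertions: list[Insertion] = field(default_factory=list)
    hairpin_loci: list[HairpinLocus] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)

    def extract(self, ins: Insertion) -> str:
        """Recover an inserted copy from genome coordinates (round-trip)."""
        seg = self.genome[ins.chrom][ins.start:ins.end]
        return revcomp(seg) if ins.strand == "-" else seg

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def locus_sequence(self, locus: HairpinLocus, flank: int = 0) -> str:
        chrom = self.genome[locus.chrom]
        return chrom[max(0, locus.start - flank):min(len(chrom), locus.end + flank)]


def _overlaps(intervals: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


def plant_insertions(families: Sequence[TeFamily],
                     chrom_lengths: Mapping[str, int],
                     copy_numbers: Mapping[str, int],
                     inverted_pair_fraction: float = 0.0,
                     genic_bias: float = 0.0,
                     seed: int = 0,
                     genes: Sequence[GeneModel] | None = None,
                     spacer_range: tuple[int, int] = (5, 50),
                     max_tries: int = 2000) -> GenomeTruth:
    """Place TE copies (and inverted-pair loci) into a fresh background genome.

    ``inverted_pair_fraction`` of each family's copies are consumed two at
    a time as juxtaposed inverted cognate copies separated by a 5-50 nt
    spacer — the alternative hairpin-forming architecture.  Single copies
    of palindromic (MITE) families are recorded as single_palindrome
    hairpin loci.  ``genic_bias`` is the probability that an insertion is
    anchored inside a gene span (requires ``genes``).
    """
    rng = np.random.default_rng(seed)
    fam_by_id = {f.family_id: f for f in families}
    chroms = list(chrom_lengths)
    background = {c: np.array(list(random_seq(n, rng))) for c, n in chrom_lengths.items()}
    total_len = sum(chrom_lengths.values())
    planned = sum(
        len(fam_by_id[fid].copies[0][0]) * n for fid, n in copy_numbers.items() if n
    )
    if planned >= 0.5 * total_len:
        raise ValueError("total inserted length exceeds 50% of genome length")

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if genes:
        for g in genes:
            occupied[g.chrom].append((g.start, g.end))  # replaced below if biased
    truth = GenomeTruth(genome={}, genes=list(genes) if genes else [])

    def place_block(length: int) -> tuple[str, int]:
        for _ in range(max_tries):
            if genes and rng.random() < genic_bias:
                g = truth.genes[rng.integers(len(truth.genes))]
                if g.end - g.start <= length:
                    continue
                chrom = g.chrom
                start = int(rng.integers(g.start, g.end - length))
                if _overlaps([iv for iv in occupied[chrom] if iv != (g.start, g.end)],
                             start, start + length):
                    continue
                return chrom, start
            else:
                chrom = chroms[rng.integers(len(chroms))]
                if chrom_lengths[chrom] <= length:
                    continue
                start = int(rng.integers(0, chrom_lengths[chrom] - length))
                if _overlaps(occupied[chrom], start, start + length):
                    continue
                return chrom, start
        raise OverflowError("cannot place insertion without overlap")

    locus_counter = 0
    for fid, n in copy_numbers.items():
        fam = fam_by_id[fid]
        if not fam.copies:
            raise ValueError(f"family {fid} has no copies")
        n_pairs = int(n * inverted_pair_fraction) // 2
        copy_iter = iter(range(n))

        def next_copy() -> str:
            i = next(copy_iter)
            return fam.copies[i % len(fam.copies)][0]

        for _ in range(n_pairs):
            c1, c2 = next_copy(), next_copy()
            spacer = random_seq(int(rng.integers(spacer_range[0], spacer_range[1] + 1)), rng)
            block = c1 + spacer + revcomp(c2)
            chrom, start = place_block(len(block))
            background[chrom][start:start + len(block)] = list(block)
            occupied[chrom].append((start, start + len(block)))
            truth.insertions.append(Insertion(fid, chrom, start, start + len(c1), "+", c1))
            truth.insertions.append(
                Insertion(fid, chrom, start + len(c1) + len(spacer),
                          start + len(block), "-", c2))
            truth.hairpin_loci.append(
                HairpinLocus(f"locus{locus_counter}", "inverted_pair",
                             chrom, start, start + len(block), fid))
            locus_counter += 1
        for _ in range(n - 2 * n_pairs):
            c = next_copy()
            strand = "+" if rng.random() < 0.5 else "-"
            written = c if strand == "+" else revcomp(c)
            chrom, start = place_block(len(c))
            background[chrom][start:start + len(c)] = list(written)
            occupied[chrom].append((start, start + len(c)))
            truth.insertions.append(Insertion(fid, chrom, start, start + len(c), strand, c))
            if fam.te_class == "MITE":
                truth.hairpin_loci.append(
                    HairpinLocus(f"locus{locus_counter}", "single_palindrome",
                                 chrom, start, start + len(c), fid))
                locus_counter += 1

    truth.genome = {c: "".join(arr) for c, arr in background.items()}
    return truth


def add_hairpin_locus(truth: GenomeTruth, family: TeFamily, copies: Sequence[str],
                      architecture: str, seed: int, locus_id: str | None = None,
                      spacer_range: tuple[int, int] = (5, 50),
                      clearance: int = 0, max_tries: int = 2000) -> HairpinLocus:
    """Write a designated hairpin locus into an existing genome truth.

    single_palindrome takes one copy; inverted_pair takes two cognate
    copies written head-to-head (second one reverse-complemented) around
    a short spacer.  Placement avoids every existing insertion, gene and
    hairpin locus.
    """
    rng = np.random.default_rng(seed)
    if architecture == "single_palindrome":
        (c,) = copies
        block, parts = c, [(c, "+", 0, len(c))]
    elif architecture == "inverted_pair":
        c1, c2 = copies
        spacer = random_seq(int(rng.integers(spacer_range[0], spacer_range[1] + 1)), rng)
        block = c1 + spacer + revcomp(c2)
        parts = [(c1, "+", 0, len(c1)), (c2, "-", len(c1) + len(spacer), len(block))]
    else:
        raise ValueError(f"invalid architecture {architecture!r}")
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in truth.genome}
    for i in truth.insertions:
        occupied[i.chrom].append((i.start, i.end))
    for g in truth.genes:
        # keep clearance room around genes for later boundary-spanning embeds
        occupied[g.chrom].append((g.start - clearance, g.end + clearance))
    chroms = list(truth.genome)
    for _ in range(max_tries):
        chrom = chroms[rng.integers(len(chroms))]
        limit = len(truth.genome[chrom]) - len(block)
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        if _overlaps(occupied[chrom], start, start + len(block)):
            continue
        seq = truth.genome[chrom]
        truth.genome[chrom] = seq[:start] + block + seq[start + len(block):]
        for copy_seq, strand, off0, off1 in parts:
            truth.insertions.append(
                Insertion(family.family_id, chrom, start + off0, start + off1, strand, copy_seq))
        lid = locus_id or f"locus{len(truth.hairpin_loci)}"
        locus = HairpinLocus(lid, architecture, chrom, start, start + len(block), family.family_id)
        truth.hairpin_loci.append(locus)
        return locus
    raise OverflowError("cannot place hairpin locus without overlap")


def make_genes(truth: GenomeTruth, n_genes: int, gene_len: int, cds_margin: int,
               descriptions: Sequence[str], seed: int = 0,
               clearance: int = 0, max_tries: int = 2000) -> list[GeneModel]:
    """Place single-exon gene models on background sequence (plus strand),
    keeping ``clearance`` nt between a gene and any existing insertion
    (room for later boundary-spanning TE embedding); appends to and
    returns truth.genes."""
    rng = np.random.default_rng(seed)
    occupied = [(i.chrom, i.start, i.end) for i in truth.insertions]
    occupied += [(g.chrom, g.start, g.end) for g in truth.genes]
    chroms = list(truth.genome)
    made = []
    for k in range(n_genes):
        for _ in range(max_tries):
            chrom = chroms[rng.integers(len(chroms))]
            limit = len(truth.genome[chrom]) - gene_len - clearance
            if limit <= clearance:
                continue
            start = int(rng.integers(clearance, limit))
            if any(c == chrom and s < start + gene_len + clearance and start - clearance < e
                   for c, s, e in occupied):
                continue
            gene = GeneModel(
                gene_id=f"gene{len(truth.genes)}", chrom=chrom,
                start=start, end=start + gene_len, strand="+",
                cds=(start + cds_margin, start + gene_len - cds_margin),
                description=descriptions[k % len(descriptions)],
            )
            truth.genes.append(gene)
            made.append(gene)
            occupied.append((chrom, start, start + gene_len))
            break
        else:
            raise OverflowError("cannot place gene without overlap")
    return made


def embed_te_in_cds(truth: GenomeTruth, gene_id: str, te_copy: str, family_id: str,
                    overlap_mode: str, orientation: str = "-",
                    inside_len: int | None = None) -> GeneModel:
    """Rewrite a gene's sequence so a cognate TE copy overlaps its CDS.

    ``boundary_spanning`` crosses exactly one CDS edge (the CDS start),
    leaving ``inside_len`` nt of the element inside the CDS and the rest
    in upstream non-coding sequence; ``fully_internal`` buries the copy
    strictly inside the CDS.  With the default antisense orientation the
    written genome segment is the reverse complement of ``te_copy``, so
    plus-strand sRNAs from the cognate hairpin find near-perfectly
    complementary sites in the transcript.
    """
    if overlap_mode not in ("boundary_spanning", "fully_internal"):
        raise ValueError(f"invalid overlap_mode {overlap_mode!r}")
    gene = truth.gene(gene_id)
    L = len(te_copy)
    if L > gene.end - gene.start:
        raise ValueError("TE longer than available gene span")
    c0, c1 = gene.cds
    if overlap_mode == "boundary_spanning":
        inside = inside_len if inside_len is not None else max(1, min(L - 1, (c1 - c0) // 2))
        if not 1 <= inside <= min(L - 1, c1 - c0 - 1):
            raise ValueError("inside_len incompatible with boundary spanning")
        start = c0 - (L - inside)
        if start < 0:
            raise ValueError("TE extends past chromosome start")
    else:
        if L >= c1 - c0 - 1:
            raise ValueError("TE too long to sit fully inside the CDS")
        start = c0 + ((c1 - c0) - L) // 2
    end = start + L
    for other in truth.insertions:
        if other.chrom == gene.chrom and other.start < end and start < other.end:
            raise ValueError("would overwrite an existing insertion")
    written = revcomp(te_copy) if orientation == "-" else te_copy
    chrom_seq = truth.genome[gene.chrom]
    truth.genome[gene.chrom] = chrom_seq[:start] + written + chrom_seq[end:]
    truth.insertions.append(Insertion(family_id, gene.chrom, start, end, orientation, te_copy))
    gene.te_overlaps_cds_boundary = overlap_mode == "boundary_spanning"
    return gene


# ---------------------------------------------------------------------------
# Small-RNA reads


@dataclass
class SrnaProfileSpec:
    """The stated world for one locus's sRNA population.

    ``strand_category`` is the planted strand-bias class; ``length_weights``
    the length spectrum over 18-30 nt (used in smeared mode and for
    background reads); ``excision`` is precise (one dominant read per
    miR/miR* window plus geometrically decaying variants) or smeared
    (reads spread ~uniformly along the locus); ``concentration`` is the
    fraction of a window's abundance carried by its dominant read.
    """

    strand_category: str = "plus_only"
    length_weights: Mapping[int, float] = field(default_factory=lambda: {24: 1.0})
    excision: str = "precise"
    mir_window: tuple[int, int] | None = None
    star_window: tuple[int, int] | None = None
    concentration: float = 0.85
    minor_strand_fraction: float | None = None

    def minus_fraction(self) -> float:
        if self.minor_strand_fraction is not None:
            return self.minor_strand_fraction
        if self.strand_category not in _MINOR_FRACTION:
            raise ValueError(f"unknown strand category {self.strand_category!r}")
        return _MINOR_FRACTION[self.strand_category]


def star_window_for(locus_len: int, mir_window: tuple[int, int]) -> tuple[int, int]:
    """miR* window paired to ``mir_window`` with 2-nt 3' overhangs, assuming
    the locus pairs position i with position locus_len-1-i (palindrome or
    inverted-pair geometry)."""
    s, e = mir_window
    s2 = locus_len + 2 - e
    return (s2, s2 + (e - s))


def _largest_remainder(weights: Mapping[int, float], total: int) -> dict[int, int]:
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    w = w / w.sum()
    raw = w * total
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: total - counts.sum()]:
        counts[i] += 1
    return dict(zip(keys, counts))


def _window_reads(locus: str, window: tuple[int, int], concentration: float) -> list[tuple[str, float]]:
    """Dominant read plus geometrically decaying shifted/trimmed variants."""
    s, e = window
    if s < 0 or e > len(locus) or s >= e:
        raise ValueError("window outside locus")
    dominant = locus[s:e]
    variants = []
    if s + 1 < e:
        variants.append(locus[s + 1:e])
    if s > 0:
        variants.append(locus[s - 1:e - 1])
    if e < len(locus):
        variants.append(locus[s + 1:e + 1])
    vw = np.array([0.5 ** (k + 1) for k in range(len(variants))])
    vw = (1 - concentration) * vw / vw.sum() if len(variants) else np.array([])
    out = [(dominant, concentration)]
    out += [(v, float(w)) for v, w in zip(variants, vw)]
    return out


def simulate_srna_reads(locus_seq: str, profile: SrnaProfileSpec, depth: int,
                        n_datasets: int, seed: int,
                        n_unique_smeared: int = 60) -> pd.DataFrame:
    """Sample an sRNA read table (sequence, dataset_id, count) for one locus.

    Each dataset is an independent multinomial resampling of a shared
    read pool at the given depth, emulating independent sequencing runs
    over the same locus.
    """
    rng = np.random.default_rng(seed)
    if not profile.length_weights:
        raise ValueError("empty length spectrum")
    minus_frac = profile.minus_fraction()
    pool: dict[tuple[str, str], float] = {}

    def add(seq: str, strand: str, weight: float) -> None:
        if weight > 0 and seq:
            key = (seq, strand)
            pool[key] = pool.get(key, 0.0) + weight

    if profile.excision == "precise":
        if profile.mir_window is None:
            raise ValueError("precise mode requires a miR window")
        star = profile.star_window or star_window_for(len(locus_seq), profile.mir_window)
        plus_weight = 1.0 - minus_frac
        for window, share in ((profile.mir_window, 0.7), (star, 0.3)):
            for seq, w in _window_reads(locus_seq, window, profile.concentration):
                add(seq, "+", plus_weight * share * w)
        if minus_frac > 0:
            # minority-strand reads: low-frequency antisense of the windows
            for window, share in ((profile.mir_window, 0.7), (star, 0.3)):
                s, e = window
                add(revcomp(locus_seq[s:e]), "-", minus_frac * share)
    elif profile.excision == "smeared":
        lengths = _largest_remainder(profile.length_weights, n_unique_smeared)
        length_list = [ln for ln, k in sorted(lengths.items()) for _ in range(k)]
        # realise the planted strand split exactly in the pool weights;
        # sampling noise then only enters through the multinomial counts
        n_minus = int(round(len(length_list) * minus_frac))
        minus_idx = set(rng.choice(len(length_list), size=n_minus, replace=False)) \
            if n_minus else set()
        for i, ln in enumerate(length_list):
            if ln >= len(locus_seq):
                raise ValueError("read length exceeds locus")
            start = int(rng.integers(0, len(locus_seq) - ln))
            frag = locus_seq[start:start + ln]
            if i in minus_idx:
                add(revcomp(frag), "-", 1.0)
            else:
                add(frag, "+", 1.0)
    else:
        raise ValueError(f"unknown excision mode {profile.excision!r}")

    keys = sorted(pool)
    weights = np.array([pool[k] for k in keys], dtype=float)
    weights /= weights.sum()
    rows = []
    for d in range(n_datasets):
        counts = rng.multinomial(depth, weights)
        for (seq, _strand), c in zip(keys, counts):
            if c > 0:
                rows.append({"sequence": seq, "dataset_id": f"ds{d}", "count": int(c)})
    df = pd.DataFrame(rows, columns=["sequence", "dataset_id", "count"])
    # one row per (sequence, dataset): merge plus/minus reads that collide
    return df.groupby(["sequence", "dataset_id"], as_index=False)["count"].sum()


# ---------------------------------------------------------------------------
# Degradome tags


def simulate_degradome(cdna: str, cleavage_pos: int, signal_reads: int,
                       noise_positions: int, noise_reads: int,
                       seed: int) -> dict[int, int]:
    """5'-tag count profile: a planted peak plus bounded background noise.

    The planted position carries ``signal_reads``; ``noise_positions``
    distinct other positions carry ``noise_reads`` tags each.
    """
    if not 0 <= cleavage_pos < len(cdna):
        raise ValueError("cleavage position out of range")
    rng = np.random.default_rng(seed)
    profile: dict[int, int] = {}
    if signal_reads > 0:
        profile[cleavage_pos] = signal_reads
    others = np.array([p for p in range(len(cdna)) if p != cleavage_pos])
    if noise_positions > len(others):
        raise ValueError("more noise positions than available sites")
    if noise_positions > 0 and noise_reads > 0:
        for p in rng.choice(others, size=noise_positions, replace=False):
            profile[int(p)] = noise_reads
    return profile
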