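"""Per-hairpin small-RNA expression profiles.

Reads are mapped to hairpins and to the genome by exact string matching
only (no mismatches, no indels), on both strands.  Each hairpin gets a
strand-bias category (plus_only / minus_only / plus_major / minus_major /
both), the unweighted mean genome hit count of its reads, and a length
distribution type (low / major21 / major24 / mixed / other) judged per
sequencing dataset.  Abundances can be normalised to transcripts per
quarter million (TPQ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .sequtil import count_occurrences, find_all, normalize, revcomp

LENGTH_RANGE = (18, 30)

SHORT_CLASS = frozenset({20, 21, 22})
LONG_CLASS = frozenset({23, 24})


@dataclass(frozen=True)
class SrnaRead:
    """A unique small-RNA sequence with per-dataset abundances."""

    sequence: str
    abundance: Mapping[str, float]

    def __post_init__(self):
        if not self.abundance:
            raise ValueError("read needs at least one dataset abundance")

    @property
    def total(self) -> float:
        return float(sum(self.abundance.values()))


def reads_from_table(df: pd.DataFrame) -> list[SrnaRead]:
    """Collapse an (sequence, dataset_id, count) table into SrnaRead objects."""
    out = []
    for seq, sub in df.groupby("sequence"):
        out.append(SrnaRead(str(seq), dict(zip(sub["dataset_id"], sub["count"].astype(float)))))
    return out


@dataclass
class Placement:
    read: SrnaRead
    strand: str
    offset: int


@dataclass
class ExpressionProfile:
    hairpin_id: str
    placements: list[Placement]
    strand_category: str
    mean_genome_hits: float
    length_type: str
    length_histograms: dict[str, dict[int, float]]
    n_zero_hit_reads: int = 0


def map_perfect(reads: Iterable[SrnaRead], hairpin: str) -> list[Placement]:
    """Every exact occurrence of each read on the hairpin (+) or on its
    reverse complement (-), with the forward offset; multi-placements kept."""
    hairpin = normalize(hairpin)
    placements: list[Placement] = []
    for read in reads:
        for off in find_all(read.sequence, hairpin):
            placements.append(Placement(read, "+", off))
        for off in find_all(revcomp(read.sequence), hairpin):
            placements.append(Placement(read, "-", off))
    return placements


def normalize_tpq(count: float, dataset_total: float) -> float:
    """Transcripts per quarter million: count * 250000 / dataset_total."""
    if dataset_total <= 0:
        raise ValueError("dataset total must be positive")
    return count * 250_000.0 / dataset_total


def strand_totals(placements: Sequence[Placement]) -> tuple[float, float]:
    """Summed abundance of reads with >= 1 placement on each strand.

    A read placing several times on one strand counts once there."""
    plus = {p.read.sequence: p.read.total for p in placements if p.strand == "+"}
    minus = {p.read.sequence: p.read.total for p in placements if p.strand == "-"}
    return sum(plus.values()), sum(minus.values())


def classify_strand_bias(placements: Sequence[Placement],
                         minor_fraction: float = 0.10) -> str:
    """Five categories from the plus/minus abundance split.

    Zero on one strand gives plus_only / minus_only; a minority strand at
    <= ``minor_fraction`` of the total gives plus_major / minus_major
    ("negligible" expression); anything else is both."""
    if not placements:
        raise ValueError("no placements")
    plus, minus = strand_totals(placements)
    if minus == 0:
        return "plus_only"
    if plus == 0:
        return "minus_only"
    frac = minus / (plus + minus)
    if frac <= minor_fraction:
        return "plus_major"
    if frac >= 1 - minor_fraction:
        return "minus_major"
    return "both"


def count_genome_hits(read_seq: str, genome: Mapping[str, str]) -> int:
    """Exact occurrences of the read over both strands of every chromosome."""
    n = 0
    for chrom_seq in genome.values():
        n += count_occurrences(read_seq, chrom_seq)
        n += count_occurrences(revcomp(read_seq), chrom_seq)
    return n


def genome_multiplicity(reads: Iterable[SrnaRead], genome: Mapping[str, str]) -> tuple[float, int]:
    """Unweighted mean genome hit count over reads with >= 1 hit.

    Returns (mean, n_zero_hit_reads); reads that never occur in the
    genome are excluded from the mean and counted separately.  The mean
    is NaN when no read hits at all."""
    hits = [count_genome_hits(r.sequence, genome) for r in reads]
    nonzero = [h for h in hits if h > 0]
    n_zero = len(hits) - len(nonzero)
    mean = float(np.mean(nonzero)) if nonzero else float("nan")
    return mean, n_zero


def length_histograms(placements: Sequence[Placement]) -> dict[str, dict[int, float]]:
    """Per-dataset {length: abundance} histograms over placed reads."""
    hists: dict[str, dict[int, float]] = {}
    seen: set[str] = set()
    for p in placements:
        if p.read.sequence in seen:
            continue
        seen.add(p.read.sequence)
        ln = len(p.read.sequence)
        for ds, ab in p.read.abundance.items():
            hists.setdefault(ds, {})
            hists[ds][ln] = hists[ds].get(ln, 0.0) + ab
    return hists


def classify_length_distribution(per_dataset_histograms: Mapping[str, Mapping[int, float]],
                                 usable_min: float = 10,
                                 major_fraction: float = 0.5) -> str:
    """Five length-distribution types judged per usable dataset.

    A dataset is usable at total abundance >= ``usable_min``; with no
    usable dataset the pattern is 'low'.  Per usable dataset the dominant
    class is short (20-22 nt) vs long (23-24 nt) vs outside 20-24 at
    abundance fraction > ``major_fraction``.  Unanimously short ->
    major21, unanimously long -> major24, any dataset dominated by
    lengths outside 20-24 -> other, disagreement or no dominant class ->
    mixed."""
    verdicts = []
    for hist in per_dataset_histograms.values():
        total = sum(hist.values())
        if total < usable_min:
            continue
        short = sum(v for ln, v in hist.items() if ln in SHORT_CLASS) / total
        long_ = sum(v for ln, v in hist.items() if ln in LONG_CLASS) / total
        other = 1.0 - short - long_
        if other > major_fraction:
            verdicts.append("other")
        elif short > major_fraction:
            verdicts.append("short")
        elif long_ > major_fraction:
            verdicts.append("long")
        else:
            verdicts.append("none")
    if not verdicts:
        return "low"
    if "other" in verdicts:
        return "other"
    if all(v == "short" for v in verdicts):
        return "major21"
    if all(v == "long" for v in verdicts):
        return "major24"
    return "mixed"


def compare_multiplicity(temir_means: Sequence[float],
                         canonical_means: Sequence[float]) -> float:
    """One-sided Mann-Whitney U p-value that TE-MIR genome multiplicities
    exceed those of canonical miRNAs."""
    if not len(temir_means) or not len(canonical_means):
        raise ValueError("both samples must be non-empty")
    pooled = list(temir_means) + list(canonical_means)
    if len(set(pooled)) == 1:
        warnings.warn("all multiplicities tied; reporting p = 1")
        return 1.0
    return float(mannwhitneyu(temir_means, canonical_means, alternative="greater").pvalue)


def aggregate_length_spectrum(profiles: Sequence[ExpressionProfile]) -> pd.DataFrame:
    """Per-dataset abundance fraction by read length over all hairpins.

    Rows are datasets, columns lengths; each row sums to 1."""
    if not profiles:
        raise ValueError("need at least one profile")
    acc: dict[str, dict[int, float]] = {}
    for prof in profiles:
        for ds, hist in prof.length_histograms.items():
            acc.setdefault(ds, {})
            for ln, v in hist.items():
                acc[ds][ln] = acc[ds].get(ln, 0.0) + v
    lengths = sorted({ln for h in acc.values() for ln in h})
    df = pd.DataFrame(
        {ln: [acc[ds].get(ln, 0.0) for ds in sorted(acc)] for ln in lengths},
        index=sorted(acc),
    )
    return df.div(df.sum(axis=1), axis=0)


def build_profile(hairpin_id: str, reads: Iterable[SrnaRead], hairpin: str,
                  genome: Mapping[str, str] | None = None,
                  minor_fraction: float = 0.10,
                  usable_min: float = 10) -> ExpressionProfile:
    """Convenience: map reads and assemble the full expression profile."""
    reads = list(reads)
    placements = map_perfect(reads, hairpin)
    if not placements:
        raise ValueError(f"no reads map to hairpin {hairpin_id}")
    placed_reads = {p.read.sequence: p.read for p in placements}
    if genome is not None:
        mean_hits, n_zero = genome_multiplicity(placed_reads.values(), genome)
    else:
        mean_hits, n_zero = float("nan"), 0
    hists = length_histograms(placements)
    return ExpressionProfile(
        hairpin_id=hairpin_id,
        placements=placements,
        strand_category=classify_strand_bias(placements, minor_fraction),
        mean_genome_hits=mean_hits,
        length_type=classify_length_distribution(hists, usable_min),
        length_histograms=hists,
        n_zero_hit_reads=n_zero,
    )
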