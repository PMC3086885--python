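"""Degradome (PARE) cleavage evidence for predicted sRNA targets.

Sliced mRNAs leave uncapped 5' ends whose first nucleotide marks the
cleavage site — for small-RNA-guided slicing, the position opposite the
tenth nucleotide from the sRNA 5' end.  Degradome 5' tags are mapped
exactly onto target cDNAs; the tag count at a predicted site is ranked
against the transcript's profile into three evidence categories
(1 = site ties the transcript maximum, 2 = above the median of expressed
positions but below the maximum, 3 = expressed but at or below the
median; median over positions with >= 1 tag only).  Detected categories
per target are summarised by a single score: category 1 contributes 4,
category 2 contributes 2, category 3 contributes 1, so {1,2,3} -> 7,
{1,2} -> 6, {1,3} -> 5, {1} -> 4, {2,3} -> 3, {2} -> 2, {3} -> 1, and 0
means no evidence.  Scores are computed per degradome dataset and never
mix counts across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequtil import find_all, normalize
from .targets import PairingAlignment, TargetPrediction

MIN_TAG_LEN = 15

_CATEGORY_WEIGHT = {1: 4, 2: 2, 3: 1}


@dataclass
class DegradomeProfile:
    """Per-position 5'-tag counts on one cDNA."""

    cdna_id: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CleavageCall:
    srna: str
    gene_id: str
    predicted_position: int
    category: int | None
    abundance_at_site: int
    transcript_max: int
    transcript_median: float


def map_tags(tags: Iterable[tuple[str, int]], cdna: str,
             cdna_id: str = "cdna") -> DegradomeProfile:
    """Exact-match tags (>= 15 nt) onto the cDNA plus strand; the 5' end
    of each occurrence defines the counted position."""
    cdna = normalize(cdna)
    profile = DegradomeProfile(cdna_id=cdna_id)
    for seq, count in tags:
        seq = normalize(seq)
        if len(seq) < MIN_TAG_LEN:
            raise ValueError(f"tag shorter than {MIN_TAG_LEN} nt")
        for pos in find_all(seq, cdna):
            profile.counts[pos] = profile.counts.get(pos, 0) + int(count)
    return profile


def profile_from_counts(cdna_id: str, counts: Mapping[int, float]) -> DegradomeProfile:
    return DegradomeProfile(cdna_id=cdna_id, counts={int(p): int(c) for p, c in counts.items() if c > 0})


def predicted_cleavage_position(alignment: PairingAlignment) -> int:
    """cDNA coordinate of the nucleotide paired to sRNA position 10."""
    idx = alignment.position_map.get(10)
    if idx is None:
        raise ValueError("sRNA position 10 falls in a bulge; no cleavage call")
    return alignment.site_start + idx


def classify_category(profile: DegradomeProfile, position: int) -> int | None:
    """Category of the tag count at ``position`` within the transcript profile.

    None when the site carries no tag.  Category 1 when the site ties the
    maximum over expressed positions (no uniqueness required); 2 when
    above the median of expressed positions but below the maximum; 3
    otherwise."""
    count = profile.counts.get(position, 0)
    if count == 0:
        return None
    expressed = [c for c in profile.counts.values() if c > 0]
    peak = max(expressed)
    median = float(np.median(expressed))
    if count == peak:
        return 1
    if count > median:
        return 2
    return 3


def summary_score(categories_detected: Iterable[int]) -> int:
    """Bit-weight summary of detected cleavage categories (0 when empty)."""
    cats = set(categories_detected)
    invalid = cats - {1, 2, 3}
    if invalid:
        raise ValueError(f"invalid categories {sorted(invalid)}")
    return sum(_CATEGORY_WEIGHT[c] for c in cats)


@dataclass
class TargetCleavageScore:
    gene_id: str
    dataset_id: str
    categories_detected: frozenset[int]
    score: int
    calls: list[CleavageCall] = field(default_factory=list)


def score_targets(predictions: Sequence[TargetPrediction],
                  degradome_sets: Mapping[str, Mapping[str, DegradomeProfile]],
                  score_max: float = 4.0) -> list[TargetCleavageScore]:
    """Per (gene, degradome dataset) summary cleavage scores.

    Gathers every prediction with pairing score <= ``score_max``,
    classifies the tag evidence at each predicted cleavage position, and
    unions the categories per target — multiple sRNAs binding one mRNA
    contribute jointly.  Datasets are scored independently.
    """
    by_gene: dict[str, list[TargetPrediction]] = {}
    for p in predictions:
        if p.score <= score_max:
            by_gene.setdefault(p.gene_id, []).append(p)
    out: list[TargetCleavageScore] = []
    for dataset_id in sorted(degradome_sets):
        profiles = degradome_sets[dataset_id]
        for gene_id in sorted(by_gene):
            profile = profiles.get(gene_id)
            if profile is None:
                continue
            calls: list[CleavageCall] = []
            cats: set[int] = set()
            for p in by_gene[gene_id]:
                try:
                    pos = predicted_cleavage_position(p.alignment)
                except ValueError:
                    continue
                cat = classify_category(profile, pos)
                expressed = [c for c in profile.counts.values() if c > 0]
                calls.append(
                    CleavageCall(
                        srna=p.srna.sequence, gene_id=gene_id,
                        predicted_position=pos, category=cat,
                        abundance_at_site=profile.counts.get(pos, 0),
                        transcript_max=max(expressed, default=0),
                        transcript_median=float(np.median(expressed)) if expressed else 0.0,
                    )
                )
                if cat is not None:
                    cats.add(cat)
            out.append(
                TargetCleavageScore(
                    gene_id=gene_id, dataset_id=dataset_id,
                    categories_detected=frozenset(cats),
                    score=summary_score(cats), calls=calls,
                )
            )
    return out


def scores_to_table(scores: Sequence[TargetCleavageScore]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": s.gene_id, "dataset_id": s.dataset_id,
            "categories": ",".join(str(c) for c in sorted(s.categories_detected)),
            "score": s.score,
        }
        for s in scores
    ]
    return pd.DataFrame(rows, columns=["gene_id", "dataset_id", "categories", "score"])
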