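"""Screening TE-homologous hairpins against plant miRNA annotation criteria.

The load-bearing criterion for calling a hairpin a bona fide miRNA gene
is precise excision of an ~21-nt miRNA/miRNA* duplex with 2-nt 3'
overhangs from the folded stem-loop; combined with genome specificity
(mean genome hit of its sRNAs <= 20) and plus-strand-restricted sRNA
production, this yields the typical/atypical verdict.  The module also
recognises locus architecture: a hairpin formed by a single palindromic
element versus one pieced together from two juxtaposed inverted cognate
TE copies, each contributing one stem arm.

Numeric thresholds here (dominance ratio, window concentration, overhang
tolerance) are operationalizations of qualitative annotation criteria
and are exposed as parameters; outputs carry them as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .fold import HairpinStructure, fold_hairpin
from .homology import DEFAULT_SCHEME, Hsp, ScoringScheme, local_align
from .profiling import ExpressionProfile, Placement
from .synthetic import TeFamily


@dataclass
class DuplexCall:
    """A candidate miR/miR* duplex on a folded hairpin."""

    hairpin_id: str
    mir_interval: tuple[int, int]
    star_interval: tuple[int, int] | None
    mir_read: str
    star_read: str | None
    dominance_ratio: float
    overhang_3p: tuple[int | None, int | None]
    window_concentration: float
    precise: bool


@dataclass
class TypicalScreenResult:
    hairpin_id: str
    passes_hit: bool
    passes_strand: bool
    passes_excision: bool

    @property
    def verdict(self) -> str:
        ok = self.passes_hit and self.passes_strand and self.passes_excision
        return "typical" if ok else "atypical"


def _interval_within(inner: tuple[int, int], outer: tuple[int, int], slop: int) -> bool:
    return inner[0] >= outer[0] - slop and inner[1] <= outer[1] + slop


def call_duplex(structure: HairpinStructure, placements: Sequence[Placement],
                hairpin_id: str = "hairpin",
                dominance_min: float = 5.0,
                window_concentration_min: float = 0.75,
                overhang_tol: int = 1,
                window_slop: int = 3) -> DuplexCall:
    """Call the dominant plus-strand read as miR and test duplex geometry.

    The miR* interval is located through the pair table on the opposite
    arm; star support is any plus-strand read whose placement matches
    that interval shifted to leave a 2-nt 3' overhang at both duplex ends
    (within ``overhang_tol``).  The call is precise when the dominance
    ratio over other overlapping reads reaches ``dominance_min``, the miR
    plus miR* windows hold >= ``window_concentration_min`` of the total
    plus-strand abundance, and the overhang geometry holds.
    """
    plus = [p for p in placements if p.strand == "+"]
    if not plus:
        raise ValueError("no plus-strand placements")
    by_read: dict[str, Placement] = {}
    for p in plus:
        if p.read.sequence not in by_read:
            by_read[p.read.sequence] = p
    top = max(by_read.values(), key=lambda p: p.read.total)
    s, e = top.offset, top.offset + len(top.read.sequence)

    # dominance over other plus-strand reads overlapping the miR window
    others = [
        p.read.total for p in by_read.values()
        if p.read.sequence != top.read.sequence and p.offset < e and s < p.offset + len(p.read.sequence)
    ]
    dominance = top.read.total / max(max(others, default=0.0), 1.0)

    # partner interval on the opposite arm via the pair table
    partners = [
        int(structure.pair_table[i]) for i in range(s, e)
        if structure.pair_table[i] >= 0 and not s <= structure.pair_table[i] < e
    ]
    star_interval = None
    star_read = None
    overhangs: tuple[int | None, int | None] = (None, None)
    geometry_ok = False
    if partners:
        lo, hi = min(partners), max(partners) + 1
        # expected star with 2-nt 3' overhangs at both duplex ends
        expected = (lo - 2, hi + 2 - 2)  # [p(e-1)-2, p(s)+2+1) shrunk to read-sized window
        for p in sorted(by_read.values(), key=lambda p: -p.read.total):
            ps, pe = p.offset, p.offset + len(p.read.sequence)
            if ps < e and s < pe:  # overlaps miR itself
                continue
            part_start = structure.partner(ps, search=2)
            part_of_mir_start = structure.partner(s, search=2)
            if part_start is None or part_of_mir_start is None:
                continue
            oh_mir = (e - 1) - part_start
            oh_star = (pe - 1) - part_of_mir_start
            if abs(oh_mir - 2) <= overhang_tol and abs(oh_star - 2) <= overhang_tol:
                star_interval = (ps, pe)
                star_read = p.read.sequence
                overhangs = (oh_mir, oh_star)
                geometry_ok = True
                break
        if star_interval is None:
            star_interval = (lo, hi)

    total_plus = sum(p.read.total for p in by_read.values())
    windows = [(s, e)]
    if star_interval is not None:
        windows.append(star_interval)
    concentrated = sum(
        p.read.total for p in by_read.values()
        if any(_interval_within((p.offset, p.offset + len(p.read.sequence)), w, window_slop)
               for w in windows)
    )
    concentration = concentrated / total_plus if total_plus else 0.0

    precise = geometry_ok and dominance >= dominance_min and concentration >= window_concentration_min
    return DuplexCall(
        hairpin_id=hairpin_id,
        mir_interval=(s, e), star_interval=star_interval,
        mir_read=top.read.sequence, star_read=star_read,
        dominance_ratio=dominance, overhang_3p=overhangs,
        window_concentration=concentration, precise=precise,
    )


def screen_typical(profile: ExpressionProfile, duplex_call: DuplexCall,
                   hit_max: float = 20.0) -> TypicalScreenResult:
    """The bona fide miRNA screen: genome hit <= hit_max, sRNAs purely or
    predominantly from the plus strand, and precise duplex excision."""
    if profile.hairpin_id != duplex_call.hairpin_id:
        raise ValueError("profile and duplex call refer to different hairpins")
    return TypicalScreenResult(
        hairpin_id=profile.hairpin_id,
        passes_hit=bool(profile.mean_genome_hits <= hit_max),
        passes_strand=profile.strand_category in ("plus_only", "plus_major"),
        passes_excision=duplex_call.precise,
    )


def _coverage(hsp: Hsp, arm: tuple[int, int]) -> float:
    a0, a1 = arm
    if a1 <= a0:
        return 0.0
    lo, hi = max(hsp.q_start, a0), min(hsp.q_end, a1)
    return max(0, hi - lo) / (a1 - a0)


def detect_inverted_te_pair(locus_seq: str, te_families: Sequence[TeFamily],
                            flank5: str = "", flank3: str = "",
                            arm_cov_min: float = 0.6,
                            scheme: ScoringScheme = DEFAULT_SCHEME,
                            e_max: float = 0.01) -> tuple[str, list[Hsp]]:
    """Classify hairpin-locus architecture against a TE family set.

    The hairpin core (``locus_seq``) is folded to locate the stem arms;
    homology search runs on the flanked sequence.  single_palindrome: one
    HSP to a family covers >= ``arm_cov_min`` of the whole two-arm span.
    inverted_pair: two non-overlapping HSPs to the same family on
    opposite strands, each covering >= ``arm_cov_min`` of one arm.
    Anything else: neither.
    """
    structure = fold_hairpin(locus_seq)
    off = len(flank5)
    arm5 = (structure.arm5[0] + off, structure.arm5[1] + off)
    arm3 = (structure.arm3[0] + off, structure.arm3[1] + off)
    span = (arm5[0], arm3[1])
    query = flank5 + locus_seq + flank3

    support: list[Hsp] = []
    for fam in te_families:
        hsps = local_align(query, fam.consensus, scheme, e_max=e_max,
                           query_id="locus", subject_id=fam.family_id, max_hsps=6)
        hsps = [h for h in hsps if h.evalue <= e_max]
        support.extend(hsps)
        for h in hsps:
            if _coverage(h, span) >= arm_cov_min:
                return "single_palindrome", [h]
        for a in hsps:
            for b in hsps:
                if a is b or a.subject_strand == b.subject_strand:
                    continue
                if a.q_end <= b.q_start or b.q_end <= a.q_start:  # non-overlapping
                    if _coverage(a, arm5) >= arm_cov_min and _coverage(b, arm3) >= arm_cov_min:
                        return "inverted_pair", [a, b]
    return "neither", support
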