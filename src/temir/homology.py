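"""Local-alignment homology search with Karlin-Altschul E-values.

This backs two screens: annotated miRNA stem-loops against a repeat/TE
library (a hairpin is called a TE-MIR when at least one high-scoring
segment pair reaches E <= 0.005), and TE-MIR hairpins against the CDS set
of protein-coding genes to recover the "initial targets" created by
cognate TE insertion (HSPs at E <= 0.05; a gene qualifies with at least
one HSP at E <= 0.01, genes annotated as hypothetical proteins excluded).

The dynamic programming itself is delegated to Biopython's
``PairwiseAligner`` (affine-gap local alignment); strand handling,
iterative masking for multiple HSPs per pair, identity computation and
the E-value statistics are implemented here.  E-values follow the
ungapped Karlin-Altschul form E = K * m * n * exp(-lambda * S) with
search-space sizes m, n equal to the raw sequence lengths.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from scipy.optimize import brentq

from .sequtil import normalize, revcomp

# Ungapped K for common blastn match/mismatch pairs (uniform background).
_K_TABLE = {(1, -2): 0.46, (1, -3): 0.711, (1, -4): 0.738, (2, -3): 0.41}
_K_FALLBACK = 0.35


def karlin_lambda(match: int, mismatch: int, p_match: float = 0.25) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0.

    With a uniform background a position matches with probability 1/4, so
    the condition reduces to p*e^(l*match) + (1-p)*e^(l*mismatch) = 1.
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 > mismatch")

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + (1 - p_match) * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 16.0))


@dataclass(frozen=True)
class ScoringScheme:
    """Integer local-alignment scoring plus its Karlin-Altschul parameters.

    Defaults mimic classic blastn: match +1, mismatch -3, affine gaps
    5/2, with lambda solved numerically and K looked up from the standard
    ungapped table.
    """

    match: int = 1
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = field(default=0.0)
    K: float = field(default=0.0)

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.lam <= 0:
            object.__setattr__(self, "lam", karlin_lambda(self.match, self.mismatch))
        if self.K <= 0:
            object.__setattr__(
                self, "K", _K_TABLE.get((self.match, self.mismatch), _K_FALLBACK)
            )


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class Hsp:
    """A high-scoring segment pair on forward coordinates (0-based half-open)."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    subject_strand: str
    raw_score: int
    evalue: float
    identity_fraction: float

    def __post_init__(self):
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("degenerate HSP interval")


def evalue_of(raw_score: float, m: int, n: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """E = K * m * n * exp(-lambda * S); monotone decreasing in S."""
    if m < 1 or n < 1:
        raise ValueError("search-space sizes must be >= 1")
    return scheme.K * m * n * math.exp(-scheme.lam * raw_score)


def min_score_for_evalue(e_max: float, m: int, n: int,
                         scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Smallest integer raw score with E <= e_max (at least one match)."""
    if e_max <= 0 or math.isinf(e_max):
        return scheme.match if math.isinf(e_max) else 10 ** 9
    s = (math.log(scheme.K * m * n) - math.log(e_max)) / scheme.lam
    return max(scheme.match, math.ceil(s - 1e-9))


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    # N never matches: score it as a mismatch against everything incl. itself.
    matrix = np.full((5, 5), float(scheme.mismatch))
    np.fill_diagonal(matrix, float(scheme.match))
    matrix[4, 4] = float(scheme.mismatch)
    from Bio.Align.substitution_matrices import Array

    aligner.substitution_matrix = Array(alphabet="ACGTN", dims=2, data=matrix)
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _best_alignment(aligner, subject: str, query: str):
    try:
        alignments = aligner.align(subject, query)
    except ValueError:
        return None
    if len(alignments) == 0:
        return None
    return alignments[0]


def local_align(query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                min_score: int | None = None, e_max: float = 10.0,
                query_id: str = "query", subject_id: str = "subject",
                max_hsps: int = 50, both_strands: bool = True) -> list[Hsp]:
    """All locally optimal, non-overlapping HSPs of query vs subject.

    The top HSP is the Smith-Waterman optimum over both subject strands;
    further HSPs come from iterative masking of the query interval of
    each accepted HSP (with N, which never matches), so reported HSPs
    occupy disjoint query regions — e.g. the two stem arms of a hairpin
    hitting the same repeat consensus on opposite strands.  Reported
    HSPs have raw score >= ``min_score`` (derived from ``e_max`` when
    omitted).
    """
    query = normalize(query)
    subject = normalize(subject)
    if not query or not subject:
        raise ValueError("empty sequence")
    m, n = len(query), len(subject)
    if min_score is None:
        min_score = min_score_for_evalue(e_max, m, n, scheme)
    aligner = _make_aligner(scheme)

    oriented_subject = {"+": subject, "-": revcomp(subject)}
    masked = list(query)
    hsps: list[Hsp] = []
    strands = ("+", "-") if both_strands else ("+",)
    while len(hsps) < max_hsps:
        current_query = "".join(masked)
        best, best_strand = None, None
        for strand in strands:
            aln = _best_alignment(aligner, oriented_subject[strand], current_query)
            if aln is not None and (best is None or aln.score > best.score):
                best, best_strand = aln, strand
        if best is None or best.score < min_score:
            break
        s_blocks, q_blocks = best.aligned
        q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
        t_start, t_end = int(s_blocks[0][0]), int(s_blocks[-1][1])
        # identity over aligned (ungapped) columns
        matches = aligned = 0
        sub_oriented = oriented_subject[best_strand]
        for (ts, te), (qs, qe) in zip(s_blocks, q_blocks):
            aligned += te - ts
            matches += sum(
                1 for a, b in zip(sub_oriented[ts:te], current_query[qs:qe]) if a == b and a != "N"
            )
        if best_strand == "+":
            s_start, s_end = t_start, t_end
        else:
            s_start, s_end = n - t_end, n - t_start
        hsps.append(
            Hsp(
                query_id=query_id, subject_id=subject_id,
                q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
                subject_strand=best_strand, raw_score=int(round(best.score)),
                evalue=evalue_of(best.score, m, n, scheme),
                identity_fraction=matches / aligned if aligned else 0.0,
            )
        )
        for i in range(q_start, q_end):
            masked[i] = "N"
    return hsps


def hsps_to_table(hsps: Iterable[Hsp]) -> pd.DataFrame:
    """BLAST-tabular-like frame (qid, sid, pident, length, coords, evalue, score)."""
    rows = [
        {
            "qid": h.query_id, "sid": h.subject_id,
            "pident": round(100.0 * h.identity_fraction, 2),
            "length": max(h.q_end - h.q_start, h.s_end - h.s_start),
            "qstart": h.q_start, "qend": h.q_end,
            "sstart": h.s_start, "send": h.s_end,
            "strand": h.subject_strand,
            "evalue": h.evalue, "raw_score": h.raw_score,
        }
        for h in hsps
    ]
    return pd.DataFrame(
        rows, columns=["qid", "sid", "pident", "length", "qstart", "qend",
                       "sstart", "send", "strand", "evalue", "raw_score"]
    )


@dataclass(frozen=True)
class TeMirCall:
    hairpin_id: str
    best_hsp: Hsp
    te_class: str


def find_te_mirs(hairpins: Mapping[str, str],
                 repeat_lib: Mapping[str, tuple[str, str]],
                 e_max: float = 0.005,
                 scheme: ScoringScheme = DEFAULT_SCHEME) -> tuple[dict[str, TeMirCall], pd.Series]:
    """Screen hairpins against a repeat library; classify TE-MIRs.

    ``repeat_lib`` maps repeat_id -> (sequence, te_class).  A hairpin is a
    TE-MIR iff it has >= 1 HSP with E <= e_max against any library entry;
    it is assigned the class of its best-E subject.  Returns the calls and
    a class frequency table (the repeat-type breakdown of the cohort).
    """
    if not repeat_lib:
        raise ValueError("empty repeat library")
    calls: dict[str, TeMirCall] = {}
    for hid, hseq in hairpins.items():
        best: Hsp | None = None
        best_class = ""
        for rid, (rseq, te_class) in repeat_lib.items():
            hsps = local_align(hseq, rseq, scheme, e_max=e_max,
                               query_id=hid, subject_id=rid, max_hsps=5)
            for h in hsps:
                if h.evalue <= e_max and (best is None or h.evalue < best.evalue):
                    best, best_class = h, te_class
        if best is not None:
            calls[hid] = TeMirCall(hairpin_id=hid, best_hsp=best, te_class=best_class)
    freq = pd.Series([c.te_class for c in calls.values()], dtype=object).value_counts()
    freq.name = "n_te_mirs"
    return calls, freq


DEFAULT_TE_KEYWORDS = (
    "transposon", "retrotransposon", "transposase", "transposable element",
    "mule", "hat", "cacta", "mudr", "helitron", "mite", "mariner", "gypsy", "copia",
)


def classify_gene_annotation(description: str,
                             te_keywords: tuple[str, ...] = DEFAULT_TE_KEYWORDS) -> str:
    """Keyword rule: TE_related / expressed_unknown / non_TE.

    Keywords match case-insensitively on word boundaries so that e.g.
    'hAT' does not fire inside unrelated words.
    """
    text = description.lower()
    for kw in te_keywords:
        if re.search(r"\b" + re.escape(kw.lower()) + r"\b", text):
            return "TE_related"
    if "expressed protein" in text or "unknown" in text:
        return "expressed_unknown"
    return "non_TE"


def is_hypothetical(description: str) -> bool:
    return "hypothetical" in description.lower()


def find_initial_targets(te_mirs: Mapping[str, str],
                         cds_set: Mapping[str, str],
                         gene_annotations: Mapping[str, str],
                         e_hsp: float = 0.05,
                         e_gene: float = 0.01,
                         scheme: ScoringScheme = DEFAULT_SCHEME) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Search TE-MIR hairpins against a CDS set for initial-target genes.

    Returns (hsp_table, initial_target_genes).  The HSP table holds every
    HSP at E <= e_hsp; a gene enters the initial-target set iff it has at
    least one HSP at E <= e_gene and is not annotated as a hypothetical
    protein.  Each kept gene carries its annotation class.
    """
    missing = [g for g in cds_set if g not in gene_annotations]
    if missing:
        raise KeyError(f"genes missing from annotations: {missing[:5]}")
    all_hsps: list[Hsp] = []
    for mid, mseq in te_mirs.items():
        for gid, cseq in cds_set.items():
            hsps = local_align(mseq, cseq, scheme, e_max=e_hsp,
                               query_id=mid, subject_id=gid, max_hsps=10)
            all_hsps.extend(h for h in hsps if h.evalue <= e_hsp)
    hsp_table = hsps_to_table(all_hsps)
    rows = []
    for gid in cds_set:
        desc = gene_annotations[gid]
        if is_hypothetical(desc):
            continue
        sub = hsp_table[(hsp_table["sid"] == gid) & (hsp_table["evalue"] <= e_gene)]
        if len(sub):
            rows.append(
                {
                    "gene_id": gid,
                    "description": desc,
                    "annotation_class": classify_gene_annotation(desc),
                    "n_hsps": int(len(sub)),
                    "min_evalue": float(sub["evalue"].min()),
                }
            )
    targets = pd.DataFrame(
        rows, columns=["gene_id", "description", "annotation_class", "n_hsps", "min_evalue"]
    )
    return hsp_table, targets
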