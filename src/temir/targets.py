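"""Plant small-RNA target prediction on CDS sequences.

Complementarity is scored with the plant (TargetFinder/Allen-style)
penalty scheme: mismatch 1, G:U wobble 0.5, bulge on either strand 2,
with every penalty doubled at sRNA positions 2-13 from the 5' end (the
core).  A candidate pair is kept when the minimized penalty total is
<= 4 and the duplex free-energy ratio against the perfectly
complementary duplex is >= 73%.  The energy proxy is a simplified
nearest-neighbor stack table (Watson-Crick + G:U stacks, terminal
penalties ignored); numerator and denominator share the table, so
systematic offsets largely cancel in the ratio.

The site search enumerates candidate windows of length |sRNA| +/- 1 (the
bounded-gap alignment allows at most one bulge per strand, which caps
the length difference at 1) with an ungapped vectorized prescreen; the
prescreen margin is generous enough that every qualifying site reaches
the full dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequtil import encode, normalize

CORE_RANGE = (2, 13)  # 1-based sRNA positions with doubled penalties

PENALTY_MISMATCH = 1.0
PENALTY_GU = 0.5
PENALTY_BULGE = 2.0

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}

#: nearest-neighbor stack pseudo-energies (kcal/mol-like), keyed by the
#: 5'-side and 3'-side pair written as sRNA-base + target-base (RNA letters).
STACK_ENERGY: dict[tuple[str, str], float] = {}
_pairs = ["AU", "CG", "GC", "UA", "GU", "UG"]
_table = [
    # AU     CG     GC     UA     GU     UG
    [-0.9, -2.2, -2.1, -1.1, -0.6, -1.4],  # AU
    [-2.1, -3.3, -2.4, -2.1, -1.4, -2.1],  # CG
    [-2.4, -3.4, -3.3, -2.2, -1.5, -2.5],  # GC
    [-1.3, -2.4, -2.1, -0.9, -1.0, -1.3],  # UA
    [-1.3, -2.5, -2.1, -1.4, -0.5, +1.3],  # GU
    [-1.0, -1.5, -1.4, -0.6, +0.3, -0.5],  # UG
]
for _i, _p in enumerate(_pairs):
    for _j, _q in enumerate(_pairs):
        STACK_ENERGY[(_p, _q)] = _table[_i][_j]


def _pair_state(s_nt: str, t_nt: str) -> str:
    if (s_nt, t_nt) in _WC:
        return "match"
    if (s_nt, t_nt) in _WOBBLE:
        return "GU"
    return "mismatch"


def _multiplier(pos1: int) -> float:
    return 2.0 if CORE_RANGE[0] <= pos1 <= CORE_RANGE[1] else 1.0


@dataclass
class PairingAlignment:
    """An anti-parallel sRNA-site pairing with its penalty score and energy.

    ``states`` walks the alignment 5'->3' along the sRNA; ``position_map``
    gives, per 1-based sRNA position, the 0-based coordinate on the site
    (None when that sRNA base is unpaired opposite a bulge).  ``site`` is
    the target subsequence 5'->3'; ``site_start`` its offset on the cDNA.
    """

    srna: str
    site: str
    states: list[str]
    score: float
    position_map: dict[int, int | None]
    mfe_observed: float
    mfe_perfect: float
    site_start: int = 0

    @property
    def mfe_ratio(self) -> float:
        return mfe_ratio(self.mfe_observed, self.mfe_perfect)


def mfe_ratio(mfe_observed: float, mfe_perfect: float) -> float:
    """100 * mfe_observed / mfe_perfect (mfe_perfect must be < 0)."""
    if mfe_perfect >= 0:
        raise ValueError("mfe_perfect must be negative")
    if mfe_observed == mfe_perfect:
        return 100.0
    return 100.0 * mfe_observed / mfe_perfect


def _rna(nt: str) -> str:
    return "U" if nt == "T" else nt


def _alignment_energy(srna: str, pair_partner: dict[int, str | None]) -> float:
    """Sum stack energies over consecutive paired sRNA positions.

    ``pair_partner`` maps 1-based sRNA position to the paired target base
    (DNA letter) or None.  A stack forms between positions i and i+1 when
    both are paired (bulged/mismatched positions break the helix)."""
    total = 0.0
    for i in range(1, len(srna)):
        a, b = pair_partner.get(i), pair_partner.get(i + 1)
        if a is None or b is None:
            continue
        p = _rna(srna[i - 1]) + _rna(a)
        q = _rna(srna[i]) + _rna(b)
        if (p, q) in STACK_ENERGY:
            total += STACK_ENERGY[(p, q)]
    return total


def perfect_duplex_energy(srna: str) -> float:
    """Energy of the sRNA paired to its perfect complement."""
    srna = normalize(srna)
    partner = {i: {"A": "T", "C": "G", "G": "C", "T": "A"}[srna[i - 1]]
               for i in range(1, len(srna) + 1)}
    return _alignment_energy(srna, partner)


def pairing_score(srna: str, site: str, max_bulges_per_strand: int = 1,
                  site_start: int = 0) -> PairingAlignment:
    """Optimal bounded-gap anti-parallel pairing of an sRNA onto a site.

    Minimizes the Allen-style penalty total over all alignments of the
    full sRNA against the full site (both consumed end to end) with at
    most ``max_bulges_per_strand`` bulges on each strand.
    """
    srna = normalize(srna)
    site = normalize(site)
    if not 18 <= len(srna) <= 26:
        raise ValueError("sRNA length must be 18-26 nt")
    if not site or abs(len(site) - len(srna)) > max_bulges_per_strand:
        raise ValueError("degenerate site for bounded-gap pairing")
    m, n = len(srna), len(site)
    r = site[::-1]  # r[j] is the target base opposite sRNA position j+1
    B = max_bulges_per_strand + 1
    INF = float("inf")
    dp = np.full((m + 1, n + 1, B, B), INF)
    dp[0, 0, 0, 0] = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            for bs in range(B):
                for bt in range(B):
                    cur = dp[i, j, bs, bt]
                    if cur == INF:
                        continue
                    if i < m and j < n:
                        state = _pair_state(srna[i], r[j])
                        pen = {"match": 0.0, "GU": PENALTY_GU, "mismatch": PENALTY_MISMATCH}[state]
                        v = cur + pen * _multiplier(i + 1)
                        if v < dp[i + 1, j + 1, bs, bt]:
                            dp[i + 1, j + 1, bs, bt] = v
                    if i < m and bs < max_bulges_per_strand:
                        v = cur + PENALTY_BULGE * _multiplier(i + 1)
                        if v < dp[i + 1, j, bs + 1, bt]:
                            dp[i + 1, j, bs + 1, bt] = v
                    if j < n and bt < max_bulges_per_strand:
                        v = cur + PENALTY_BULGE * _multiplier(max(i, 1))
                        if v < dp[i, j + 1, bs, bt + 1]:
                            dp[i, j + 1, bs, bt + 1] = v
    ends = dp[m, n]
    bs, bt = np.unravel_index(int(np.argmin(ends)), ends.shape)
    score = float(ends[bs, bt])

    # traceback
    states: list[str] = []
    position_map: dict[int, int | None] = {}
    i, j = m, n
    bs, bt = int(bs), int(bt)
    while i > 0 or j > 0:
        cur = dp[i, j, bs, bt]
        if i > 0 and j > 0:
            state = _pair_state(srna[i - 1], r[j - 1])
            pen = {"match": 0.0, "GU": PENALTY_GU, "mismatch": PENALTY_MISMATCH}[state]
            if np.isclose(dp[i - 1, j - 1, bs, bt] + pen * _multiplier(i), cur):
                states.append(state)
                position_map[i] = n - 1 - (j - 1)  # site coordinate 5'->3'
                i, j = i - 1, j - 1
                continue
        if i > 0 and bs > 0 and np.isclose(
                dp[i - 1, j, bs - 1, bt] + PENALTY_BULGE * _multiplier(i), cur):
            states.append("bulge_srna")
            position_map[i] = None
            i, bs = i - 1, bs - 1
            continue
        if j > 0 and bt > 0 and np.isclose(
                dp[i, j - 1, bs, bt - 1] + PENALTY_BULGE * _multiplier(max(i, 1)), cur):
            states.append("bulge_target")
            j, bt = j - 1, bt - 1
            continue
        raise RuntimeError("pairing traceback failed")
    states.reverse()

    partner = {
        pos: (site[idx] if idx is not None else None)
        for pos, idx in position_map.items()
    }
    for pos, st in _mismatch_positions(states):
        if st == "mismatch":
            partner[pos] = None  # a mismatch breaks the helix for stacking
    observed = _alignment_energy(srna, partner)
    return PairingAlignment(
        srna=srna, site=site, states=states, score=score,
        position_map=position_map, mfe_observed=observed,
        mfe_perfect=perfect_duplex_energy(srna), site_start=site_start,
    )


def _mismatch_positions(states: Sequence[str]) -> list[tuple[int, str]]:
    out = []
    pos = 0
    for st in states:
        if st != "bulge_target":
            pos += 1
        if st == "mismatch":
            out.append((pos, st))
    return out


def duplex_mfe(srna: str, site: str) -> float:
    """Intermolecular duplex energy proxy for the optimal pairing."""
    return pairing_score(srna, site).mfe_observed


@dataclass(frozen=True)
class SrnaRecord:
    """An sRNA with its hairpin of origin and strand."""

    sequence: str
    hairpin_id: str
    strand: str = "+"
    abundance: float = 0.0


@dataclass
class TargetPrediction:
    srna: SrnaRecord
    gene_id: str
    site_start: int
    site_end: int
    alignment: PairingAlignment

    @property
    def score(self) -> float:
        return self.alignment.score

    @property
    def mfe_ratio(self) -> float:
        return self.alignment.mfe_ratio


# penalty lookup for the ungapped prescreen, indexed by encoded bases
_PRE = np.full((5, 5), PENALTY_MISMATCH)
for (_a, _b) in _WC:
    _PRE["ACGT".index(_a), "ACGT".index(_b)] = 0.0
for (_a, _b) in _WOBBLE:
    _PRE["ACGT".index(_a), "ACGT".index(_b)] = PENALTY_GU


def _prescreen(srna: str, target: str) -> np.ndarray:
    """Ungapped core-weighted penalty of the sRNA at every target offset."""
    m, n = len(srna), len(target)
    if n < m:
        return np.full(0, np.inf)
    es = encode(srna).astype(np.int64)
    et = encode(target).astype(np.int64)
    n_off = n - m + 1
    total = np.zeros(n_off)
    for i in range(m):
        total += _multiplier(i + 1) * _PRE[es[i], et[m - 1 - i:m - 1 - i + n_off]]
    return total


def predict_targets(srnas: Iterable[SrnaRecord], cds_set: Mapping[str, str],
                    score_max: float = 4.0, ratio_min: float = 73.0,
                    strands: str = "plus", prescreen_margin: float = 6.0) -> list[TargetPrediction]:
    """Scan every CDS for sites of every sRNA; keep pairs at the thresholds.

    ``strands`` = 'plus' restricts to sRNAs from the plus strand of their
    hairpin (the conventional choice); 'both' admits all.
    """
    if strands not in ("plus", "both"):
        raise ValueError("strands must be 'plus' or 'both'")
    predictions: list[TargetPrediction] = []
    for gid, cds in cds_set.items():
        cds = normalize(cds)
        for rec in srnas:
            if strands == "plus" and rec.strand != "+":
                continue
            s = normalize(rec.sequence)
            m = len(s)
            if len(cds) < m - 1:
                continue
            pre = _prescreen(s, cds)
            candidates = np.nonzero(pre <= score_max + prescreen_margin)[0]
            best_here: list[TargetPrediction] = []
            for o in candidates:
                for wlen in (m - 1, m, m + 1):
                    if o + wlen > len(cds) or wlen <= 0:
                        continue
                    aln = pairing_score(s, cds[o:o + wlen], site_start=int(o))
                    if aln.score <= score_max and aln.mfe_ratio >= ratio_min:
                        best_here.append(TargetPrediction(rec, gid, int(o), int(o + wlen), aln))
            # suppress overlapping windows, keep the best-scoring site
            best_here.sort(key=lambda p: (p.score, -p.mfe_ratio))
            kept: list[TargetPrediction] = []
            for p in best_here:
                if all(p.site_end <= q.site_start or q.site_end <= p.site_start
                       for q in kept):
                    kept.append(p)
            predictions.extend(kept)
    return predictions


def predictions_to_table(predictions: Sequence[TargetPrediction]) -> pd.DataFrame:
    """Predictions TSV shape: 1-based inclusive site coordinates on the cDNA."""
    rows = [
        {
            "srna": p.srna.sequence, "hairpin_id": p.srna.hairpin_id,
            "strand": p.srna.strand, "gene_id": p.gene_id,
            "site_start": p.site_start + 1, "site_end": p.site_end,
            "score": p.score, "mfe_ratio": round(p.mfe_ratio, 2),
        }
        for p in predictions
    ]
    return pd.DataFrame(rows, columns=["srna", "hairpin_id", "strand", "gene_id",
                                       "site_start", "site_end", "score", "mfe_ratio"])


def build_interaction_matrix(hsp_table: pd.DataFrame,
                             predictions: Sequence[TargetPrediction],
                             gene_classes: Mapping[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The TE-MIR x initial-target interaction matrix with MTPH flags.

    A cell (MIR, gene) holding >= 1 HSP is an MTPH (MIR-Target Pair HSP)
    iff at least one sRNA from that TE-MIR has a kept prediction on that
    gene's CDS.  Also returns the per-annotation-class MTPH-rate summary.
    """
    predicted_pairs = {(p.srna.hairpin_id, p.gene_id) for p in predictions}
    pred_ids = {p.srna.hairpin_id for p in predictions} | {p.gene_id for p in predictions}
    known = set(hsp_table["qid"]) | set(hsp_table["sid"])
    dangling = pred_ids - known - set(gene_classes)
    if dangling:
        raise KeyError(f"prediction ids absent from HSP table/classes: {sorted(dangling)[:5]}")
    rows = []
    for (mir, gene), sub in hsp_table.groupby(["qid", "sid"]):
        best = sub.loc[sub["evalue"].idxmin()]
        rows.append(
            {
                "mir_id": mir, "gene_id": gene, "n_hsps": int(len(sub)),
                "min_evalue": float(sub["evalue"].min()),
                "mtph": (mir, gene) in predicted_pairs,
                "best_raw_score": int(best["raw_score"]),
                "gene_class": gene_classes.get(gene, "non_TE"),
            }
        )
    cells = pd.DataFrame(rows, columns=["mir_id", "gene_id", "n_hsps", "min_evalue",
                                        "mtph", "best_raw_score", "gene_class"])
    if len(cells):
        summary = (
            cells.groupby("gene_class")
            .agg(n_pairs=("mtph", "size"), n_mtph=("mtph", "sum"))
            .reset_index()
        )
        summary["mtph_rate"] = summary["n_mtph"] / summary["n_pairs"]
    else:
        summary = pd.DataFrame(columns=["gene_class", "n_pairs", "n_mtph", "mtph_rate"])
    return cells, summary
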