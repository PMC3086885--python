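"""Local alignment, Karlin-Altschul statistics and the two homology screens."""

import math

import pytest

from temir.homology import (
    DEFAULT_SCHEME,
    ScoringScheme,
    classify_gene_annotation,
    evalue_of,
    find_initial_targets,
    find_te_mirs,
    karlin_lambda,
    local_align,
    min_score_for_evalue,
)
from temir.sequtil import revcomp
from temir.synthetic import generate_te_family

from oracles import exhaustive_local_score, sw_best_score


class TestLocalAlign:
    def test_self_alignment_is_perfect(self):
        hsps = local_align("ACGTACGTACGT", "ACGTACGTACGT", min_score=5)
        assert hsps[0].raw_score == 12
        assert hsps[0].identity_fraction == 1.0
        assert hsps[0].subject_strand == "+"

    def test_reverse_complement_hits_minus_strand(self):
        q = "ACGTTGCAGGTTACTG"
        hsps = local_align(q, revcomp(q), min_score=5)
        top = hsps[0]
        assert top.subject_strand == "-"
        assert top.raw_score == len(q)
        assert (top.s_start, top.s_end) == (0, len(q))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    @pytest.mark.parametrize("length", [12, 20, 30])
    def test_matches_independent_smith_waterman(self, rng, random_dna, length):
        """Top HSP score equals a hand-written affine SW over both strands."""
        for _ in range(40):
            q, s = random_dna(length), random_dna(length)
            expected = max(sw_best_score(q, s), sw_best_score(q, revcomp(s)))
            hsps = local_align(q, s, min_score=1)
            got = hsps[0].raw_score if hsps else 0
            assert got == expected, (q, s)

    def test_matches_exhaustive_substring_enumeration(self, random_dna):
        """At tiny n the SW optimum equals brute force over all substring pairs."""
        for _ in range(8):
            q, s = random_dna(9), random_dna(9)
            expected = max(exhaustive_local_score(q, s),
                           exhaustive_local_score(q, revcomp(s)))
            hsps = local_align(q, s, min_score=1)
            got = hsps[0].raw_score if hsps else 0
            assert got == expected

    def test_strand_involution(self, random_dna):
        """Against the reverse complement: same score, flipped strand,
        mirrored subject coordinates."""
        shared = random_dna(25)
        q = random_dna(20) + shared + random_dna(15)
        s = random_dna(30) + shared + random_dna(25)
        fwd = local_align(q, s, min_score=8)
        rev = local_align(q, revcomp(s), min_score=8)
        a, b = fwd[0], rev[0]
        assert a.raw_score == b.raw_score
        assert a.subject_strand != b.subject_strand
        assert (a.s_start, a.s_end) == (len(s) - b.s_end, len(s) - b.s_start)

    def test_multiple_hsps_occupy_disjoint_query_regions(self, random_dna):
        core = random_dna(40)
        query = core + random_dna(30) + core
        hsps = local_align(query, core, min_score=20)
        assert len(hsps) >= 2
        for i, a in enumerate(hsps):
            for b in hsps[i + 1:]:
                assert a.q_end <= b.q_start or b.q_end <= a.q_start


class TestEvalue:
    def test_direct_formula(self):
        scheme = ScoringScheme(match=1, mismatch=-2, lam=1.28, K=0.46)
        expected = 0.46 * 120 * 1e5 * math.exp(-1.28 * 20)
        assert evalue_of(20, 120, 10**5, scheme) == pytest.approx(expected)

    def test_monotone_and_linear(self):
        e1 = evalue_of(20, 100, 1000)
        assert evalue_of(30, 100, 1000) < e1
        assert evalue_of(20, 100, 2000) == pytest.approx(2 * e1)
        assert evalue_of(10**4, 100, 1000) == pytest.approx(0.0, abs=1e-300)

    def test_lambda_solves_karlin_equation(self):
        lam = karlin_lambda(1, -3)
        assert 0.25 * math.exp(lam) + 0.75 * math.exp(-3 * lam) == pytest.approx(1.0)

    def test_search_space_must_be_positive(self):
        with pytest.raises(ValueError):
            evalue_of(10, 0, 100)

    def test_null_calibration_bound(self, rng, random_dna):
        """Karlin-Altschul conservatism: HSPs at E <= t against shuffled
        subjects occur no more than ~3 t per subject."""
        query = random_dna(120)
        n_subjects = 200
        for t in (0.05, 0.005):
            count = 0
            for _ in range(n_subjects):
                subject = random_dna(150)
                hsps = local_align(query, subject, e_max=t, max_hsps=3)
                count += sum(1 for h in hsps if h.evalue <= t)
            assert count <= max(3 * t * n_subjects, 1)


class TestTeMirScreen:
    def test_planted_mite_detected_and_classified(self, random_dna):
        fam = generate_te_family("MITE", 200, 14, 1, 0.05, 3, family_id="mite1")
        decoy = generate_te_family("retrotransposon", 250, 0, 1, 0.0, 4, family_id="rt1")
        hairpin = random_dna(60) + fam.copies[0][0] + random_dna(60)
        lib = {"mite1": (fam.consensus, "MITE"), "rt1": (decoy.consensus, "retrotransposon")}
        calls, freq = find_te_mirs({"h1": hairpin, "h2": random_dna(300)}, lib)
        assert set(calls) == {"h1"}
        assert calls["h1"].te_class == "MITE"
        assert freq["MITE"] == 1

    def test_random_hairpins_rarely_pass_default_threshold(self, random_dna):
        lib = {f"r{i}": (random_dna(200), "MITE") for i in range(5)}
        hairpins = {f"h{i}": random_dna(300) for i in range(20)}
        calls, _ = find_te_mirs(hairpins, lib, e_max=0.005)
        assert len(calls) <= 1  # expected false positives ~ e_max per pair

    def test_infinite_threshold_reports_any_hsp(self, random_dna):
        lib = {"r": (random_dna(200), "MITE")}
        hairpins = {f"h{i}": random_dna(200) for i in range(5)}
        calls, _ = find_te_mirs(hairpins, lib, e_max=float("inf"))
        assert len(calls) == 5

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            find_te_mirs({"h": "ACGT" * 20}, {})


class TestInitialTargets:
    def test_planted_cognate_fragment_recovered(self, rng, random_dna):
        fam = generate_te_family("MITE", 200, 14, 2, 0.03, 9)
        te_mir = random_dna(30) + fam.copies[0][0] + random_dna(30)
        fragment = fam.copies[1][0][:150]
        cds = {
            "geneA": random_dna(80) + revcomp(fragment) + random_dna(80),
            "geneB": random_dna(300),
        }
        annot = {"geneA": "MYB family transcription factor", "geneB": "expressed protein"}
        hsp_table, targets = find_initial_targets({"mir1": te_mir}, cds, annot)
        assert list(targets["gene_id"]) == ["geneA"]
        assert targets.iloc[0]["annotation_class"] == "non_TE"
        assert (hsp_table["evalue"] <= 0.05).all()

    def test_hypothetical_proteins_excluded(self, random_dna):
        frag = random_dna(150)
        te_mir = frag + random_dna(50)
        cds = {"geneH": random_dna(50) + frag + random_dna(50)}
        annot = {"geneH": "hypothetical protein"}
        hsp_table, targets = find_initial_targets({"m": te_mir}, cds, annot)
        assert len(hsp_table) >= 1  # the homology is real ...
        assert len(targets) == 0  # ... but the gene is filtered

    def test_vanishing_gene_threshold_empties_target_set(self, random_dna):
        frag = random_dna(150)
        cds = {"g": frag + random_dna(50)}
        _, targets = find_initial_targets(
            {"m": frag}, cds, {"g": "expressed protein"}, e_gene=1e-300)
        assert len(targets) == 0

    def test_missing_annotation_is_an_error(self, random_dna):
        with pytest.raises(KeyError):
            find_initial_targets({"m": random_dna(100)}, {"g": random_dna(100)}, {})


@pytest.mark.parametrize(
    "description,expected",
    [
        ("retrotransposon protein, putative", "TE_related"),
        ("transposon protein, putative, CACTA, En/Spm sub-class", "TE_related"),
        ("hAT dimerisation domain containing protein", "TE_related"),
        ("expressed protein", "expressed_unknown"),
        ("unknown protein", "expressed_unknown"),
        ("MYB family transcription factor", "non_TE"),
        ("heat shock protein 70", "non_TE"),
    ],
)
def test_gene_annotation_keyword_classes(description, expected):
    assert classify_gene_annotation(description) == expected


try:
    from hypothesis import given, settings, strategies as st

    dna = st.text(alphabet="ACGT", min_size=6, max_size=20)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(q=dna, s=dna)
    def test_property_local_align_equals_oracle(q, s):
        """For arbitrary short sequences the top HSP equals the independent
        Smith-Waterman oracle maximised over both subject strands."""
        expected = max(sw_best_score(q, s), sw_best_score(q, revcomp(s)))
        hsps = local_align(q, s, min_score=1)
        assert (hsps[0].raw_score if hsps else 0) == expected
except ImportError:  # pragma: no cover
    pass


def test_min_score_for_evalue_inverts_the_formula():
    s = min_score_for_evalue(0.005, 200, 300, DEFAULT_SCHEME)
    assert evalue_of(s, 200, 300) <= 0.005
    assert evalue_of(s - 1, 200, 300) > 0.005
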