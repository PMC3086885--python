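"""Ground-truth generator: TE families, genome planting, reads, degradome."""

import numpy as np
import pandas as pd
import pytest

from temir.sequtil import revcomp
from temir.synthetic import (
    GeneModel,
    SrnaProfileSpec,
    TeFamily,
    embed_te_in_cds,
    generate_te_family,
    make_genes,
    plant_insertions,
    simulate_degradome,
    simulate_srna_reads,
    speciate_hairpin_copy,
    star_window_for,
)


class TestTeFamily:
    def test_zero_divergence_copies_identical(self):
        fam = generate_te_family("MITE", 260, 14, 1, 0.0, 5)
        assert fam.copies[0][0] == fam.consensus
        assert fam.consensus[:14] == revcomp(fam.consensus[-14:])

    def test_divergence_sets_mean_identity(self):
        """Binomial expectation: 5% substitution rate -> ~95% identity."""
        fam = generate_te_family("MITE", 260, 14, 50, 0.05, 5)
        idents = [
            sum(a == b for a, b in zip(c, fam.consensus)) / 260 for c, _ in fam.copies
        ]
        assert np.mean(idents) == pytest.approx(0.95, abs=0.02)

    def test_non_mite_termini_not_palindromic(self):
        fam = generate_te_family("retrotransposon", 300, 0, 10, 0.1, 7)
        assert fam.consensus[:14] != revcomp(fam.consensus[-14:])

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(te_class="plasmid", length=200, tir_len=0, n_copies=1, divergence=0.0, seed=1),
            dict(te_class="MITE", length=40, tir_len=14, n_copies=1, divergence=0.0, seed=1),
            dict(te_class="MITE", length=200, tir_len=14, n_copies=1, divergence=0.5, seed=1),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_te_family(**kwargs)

    def test_mite_invariant_enforced_on_construction(self):
        with pytest.raises(ValueError):
            TeFamily("bad", "MITE", "AAAACCCC" * 10, 12)

    def test_deterministic_for_fixed_seed(self):
        a = generate_te_family("MITE", 200, 20, 5, 0.1, 99)
        b = generate_te_family("MITE", 200, 20, 5, 0.1, 99)
        assert a.consensus == b.consensus and a.copies == b.copies


class TestPlantInsertions:
    def test_single_insertion_recorded(self):
        fam = generate_te_family("other_DNA", 150, 0, 1, 0.0, 1, family_id="famA")
        truth = plant_insertions([fam], {"chr1": 5000}, {"famA": 1})
        assert len(truth.insertions) == 1
        ins = truth.insertions[0]
        assert 0 <= ins.start < ins.end <= 5000

    def test_inverted_pair_fraction_one_makes_pairs(self):
        fam = generate_te_family("retrotransposon", 120, 0, 10, 0.02, 2, family_id="famA")
        truth = plant_insertions([fam], {"chr1": 20000}, {"famA": 10},
                                 inverted_pair_fraction=1.0, seed=3)
        pair_loci = [h for h in truth.hairpin_loci if h.architecture == "inverted_pair"]
        assert len(pair_loci) == 5
        assert len(truth.insertions) == 10
        for k in range(0, 10, 2):
            a, b = truth.insertions[k], truth.insertions[k + 1]
            assert a.family_id == b.family_id
            assert {a.strand, b.strand} == {"+", "-"}
            assert 5 <= b.start - a.end <= 50  # spacer

    def test_genic_bias_one_targets_the_gene(self):
        fam = generate_te_family("MITE", 100, 12, 5, 0.0, 4, family_id="famA")
        gene = GeneModel("g1", "chr1", 2000, 6000, "+", (2200, 5800), "expressed protein")
        truth = plant_insertions([fam], {"chr1": 20000}, {"famA": 5},
                                 genic_bias=1.0, genes=[gene], seed=5)
        for ins in truth.insertions:
            assert ins.start < gene.end and gene.start < ins.end

    def test_round_trip_extraction(self):
        """Every inserted copy is recoverable from genome coordinates."""
        fams = [
            generate_te_family("MITE", 150, 15, 6, 0.05, 6, family_id="A"),
            generate_te_family("retrotransposon", 200, 0, 4, 0.1, 7, family_id="B"),
        ]
        truth = plant_insertions(fams, {"chr1": 30000, "chr2": 10000},
                                 {"A": 6, "B": 4}, inverted_pair_fraction=0.5, seed=8)
        for ins in truth.insertions:
            assert truth.extract(ins) == ins.sequence

    def test_overflow_rejected(self):
        fam = generate_te_family("MITE", 600, 15, 2, 0.0, 9, family_id="A")
        with pytest.raises(ValueError):
            plant_insertions([fam], {"chr1": 2000}, {"A": 2})

    def test_seed_determinism(self):
        fam = generate_te_family("MITE", 150, 15, 4, 0.05, 10, family_id="A")
        t1 = plant_insertions([fam], {"chr1": 10000}, {"A": 4}, seed=11)
        t2 = plant_insertions([fam], {"chr1": 10000}, {"A": 4}, seed=11)
        assert t1.genome == t2.genome
        assert t1.insertions == t2.insertions


class TestEmbedTeInCds:
    def _world(self):
        fam = generate_te_family("MITE", 120, 12, 2, 0.0, 12, family_id="A")
        truth = plant_insertions([fam], {"chr1": 20000}, {"A": 0}, seed=13)
        make_genes(truth, 2, 500, 60, ["expressed protein", "kinase"], seed=14,
                   clearance=150)
        return truth, fam

    def test_boundary_spanning_crosses_exactly_one_cds_edge(self):
        truth, fam = self._world()
        gene = embed_te_in_cds(truth, "gene0", fam.copies[0][0], "A", "boundary_spanning")
        ins = truth.insertions[-1]
        c0, c1 = gene.cds
        assert max(ins.start, c0) < min(ins.end, c1)  # intersects the CDS
        assert ins.start < c0 and ins.end <= c1  # extends into non-coding
        assert gene.te_overlaps_cds_boundary

    def test_fully_internal_is_contained(self):
        truth, fam = self._world()
        gene = embed_te_in_cds(truth, "gene0", fam.copies[0][0], "A", "fully_internal")
        ins = truth.insertions[-1]
        assert gene.cds[0] < ins.start and ins.end < gene.cds[1]
        assert not gene.te_overlaps_cds_boundary

    def test_te_longer_than_gene_rejected(self):
        truth, _ = self._world()
        with pytest.raises(ValueError):
            embed_te_in_cds(truth, "gene0", "ACGT" * 200, "A", "boundary_spanning")

    def test_antisense_embedding_writes_reverse_complement(self):
        truth, fam = self._world()
        embed_te_in_cds(truth, "gene1", fam.copies[0][0], "A", "fully_internal",
                        orientation="-")
        ins = truth.insertions[-1]
        segment = truth.genome[ins.chrom][ins.start:ins.end]
        assert segment == revcomp(fam.copies[0][0])
        assert truth.extract(ins) == fam.copies[0][0]


class TestSpeciateHairpinCopy:
    def test_duplex_mismatches_break_minus_strand_self_match(self):
        fam = generate_te_family("MITE", 200, 80, 1, 0.0, 21, family_id="A")
        for seed in range(20):
            copy = speciate_hairpin_copy(fam, (10, 31), seed=seed)
            mir = copy[10:31]
            assert revcomp(mir) not in copy
            star = star_window_for(len(copy), (10, 31))
            assert revcomp(copy[star[0]:star[1]]) not in copy


class TestSimulateSrnaReads:
    def _spec(self, **kw):
        base = dict(strand_category="plus_only", excision="precise", mir_window=(20, 41))
        base.update(kw)
        return SrnaProfileSpec(**base)

    def test_plus_only_precise_has_no_minus_reads(self, typical_locus):
        locus = typical_locus["locus"]
        df = simulate_srna_reads(locus, self._spec(mir_window=(20, 44)), 1000, 1, seed=1)
        for seq in df["sequence"]:
            assert revcomp(seq) not in locus or seq in locus
            assert seq in locus  # all plus-strand fragments
        assert df["sequence"].str.len().mode()[0] == 24

    def test_dominant_read_at_least_five_fold(self, typical_locus):
        df = simulate_srna_reads(typical_locus["locus"], self._spec(), 1000, 1, seed=2)
        mir = typical_locus["locus"][20:41]
        counts = df.groupby("sequence")["count"].sum()
        others = counts.drop(index=mir, errors="ignore")
        overlapping = [c for s, c in others.items()
                       if s in typical_locus["locus"][17:44]]
        assert counts[mir] >= 5 * max(overlapping, default=1)

    def test_smeared_both_strands_balanced(self, random_dna):
        locus = random_dna(250)
        spec = self._spec(strand_category="both", excision="smeared",
                          length_weights={21: 0.5, 24: 0.5})
        df = simulate_srna_reads(locus, spec, 1000, 1, seed=3)
        minus = df[df["sequence"].map(lambda s: s not in locus)]["count"].sum()
        frac = minus / df["count"].sum()
        assert 0.35 <= frac <= 0.65

    def test_length_spectrum_fidelity(self, random_dna):
        """At depth 1e4 empirical length frequencies land within +/-3 points."""
        weights = {21: 0.25, 22: 0.1, 24: 0.55, 18: 0.1}
        spec = self._spec(strand_category="plus_only", excision="smeared",
                          length_weights=weights)
        df = simulate_srna_reads(random_dna(300), spec, 10_000, 1, seed=4)
        by_len = df.assign(length=df["sequence"].str.len()).groupby("length")["count"].sum()
        fracs = by_len / by_len.sum()
        for ln, w in weights.items():
            assert fracs.get(ln, 0.0) == pytest.approx(w, abs=0.03)

    def test_window_outside_locus_rejected(self, random_dna):
        with pytest.raises(ValueError):
            simulate_srna_reads(random_dna(100), self._spec(mir_window=(90, 111)), 100, 1, 5)

    def test_empty_spectrum_rejected(self, random_dna):
        spec = self._spec(excision="smeared", length_weights={})
        with pytest.raises(ValueError):
            simulate_srna_reads(random_dna(100), spec, 100, 1, 5)

    def test_datasets_resample_shared_pool(self, typical_locus):
        df = simulate_srna_reads(typical_locus["locus"], self._spec(), 500, 3, seed=6)
        assert set(df["dataset_id"]) == {"ds0", "ds1", "ds2"}
        per_ds = df.groupby("dataset_id")["count"].sum()
        assert (per_ds == 500).all()

    def test_byte_identical_for_fixed_seed(self, typical_locus):
        a = simulate_srna_reads(typical_locus["locus"], self._spec(), 500, 2, seed=7)
        b = simulate_srna_reads(typical_locus["locus"], self._spec(), 500, 2, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateDegradome:
    def test_clean_peak(self, random_dna):
        prof = simulate_degradome(random_dna(200), 88, 50, 0, 0, seed=1)
        assert prof == {88: 50}

    def test_peak_dominates_noise(self, random_dna):
        prof = simulate_degradome(random_dna(200), 88, 50, 10, 5, seed=2)
        assert max(prof, key=prof.get) == 88
        assert sum(1 for p in prof if p != 88) == 10
        assert all(c <= 5 for p, c in prof.items() if p != 88)

    def test_tie_by_construction(self, random_dna):
        prof = simulate_degradome(random_dna(200), 30, 3, 1, 3, seed=3)
        counts = sorted(prof.values())
        assert counts == [3, 3]

    def test_position_out_of_range(self, random_dna):
        with pytest.raises(ValueError):
            simulate_degradome(random_dna(50), 50, 10, 0, 0, seed=1)
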