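"""Read mapping, TPQ, strand bias, genome multiplicity and length types."""

import numpy as np
import pytest

from temir.profiling import (
    Placement,
    SrnaRead,
    aggregate_length_spectrum,
    build_profile,
    classify_length_distribution,
    classify_strand_bias,
    compare_multiplicity,
    genome_multiplicity,
    map_perfect,
    normalize_tpq,
)
from temir.sequtil import revcomp
from temir.synthetic import SrnaProfileSpec, generate_te_family, plant_insertions, simulate_srna_reads


def _read(seq, total=10.0, ds="d0"):
    return SrnaRead(seq, {ds: total})


class TestMapPerfect:
    def test_plus_strand_substring(self, random_dna):
        hp = random_dna(100)
        placements = map_perfect([_read(hp[10:31])], hp)
        assert [(p.strand, p.offset) for p in placements] == [("+", 10)]

    def test_minus_strand_substring(self, random_dna):
        hp = random_dna(100)
        placements = map_perfect([_read(revcomp(hp[40:64]))], hp)
        assert [(p.strand, p.offset) for p in placements] == [("-", 40)]

    def test_single_mismatch_never_places(self, random_dna):
        hp = random_dna(100)
        read = list(hp[10:31])
        read[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[10]]
        assert map_perfect([_read("".join(read))], hp) == []

    def test_multi_placement_read(self, random_dna):
        unit = random_dna(25)
        hp = unit + random_dna(10) + unit
        placements = map_perfect([_read(unit)], hp)
        assert [p.offset for p in placements] == [0, 35]


def test_normalize_tpq_examples():
    assert normalize_tpq(4, 1_000_000) == 1.0
    assert normalize_tpq(250_000, 250_000) == 250_000
    assert normalize_tpq(0, 10) == 0.0
    with pytest.raises(ValueError):
        normalize_tpq(5, 0)


class TestStrandBias:
    def _placements(self, plus, minus):
        out = []
        for i, ab in enumerate(plus):
            out.append(Placement(_read("A" * (21 + i % 2) + "C" * i, ab), "+", i))
        for i, ab in enumerate(minus):
            out.append(Placement(_read("G" * (21 + i % 2) + "T" * i, ab), "-", i))
        return out

    def test_categories(self):
        assert classify_strand_bias(self._placements([500], [])) == "plus_only"
        assert classify_strand_bias(self._placements([], [500])) == "minus_only"
        assert classify_strand_bias(self._placements([500], [20])) == "plus_major"
        assert classify_strand_bias(self._placements([20], [500])) == "minus_major"
        assert classify_strand_bias(self._placements([300], [280])) == "both"

    def test_no_placements_rejected(self):
        with pytest.raises(ValueError):
            classify_strand_bias([])


class TestGenomeMultiplicity:
    def test_unique_read(self, random_dna):
        genome = {"chr1": random_dna(5000)}
        read = _read(genome["chr1"][100:121])
        mean, n_zero = genome_multiplicity([read], genome)
        assert mean == 1.0 and n_zero == 0

    def test_mean_over_mixed_hits(self, random_dna):
        g = random_dna(2000)
        triple = g[50:71]
        genome = {"chr1": g + triple + "ACGT" + triple}
        mean, _ = genome_multiplicity([_read(triple), _read(g[500:521])], genome)
        assert mean == 2.0  # hits {3, 1}

    def test_planted_copies_drive_multiplicity(self):
        """Reads from a TE planted at 50 identical copies hit ~50 sites."""
        fam = generate_te_family("retrotransposon", 120, 0, 1, 0.0, 3, family_id="A")
        truth = plant_insertions([fam], {"chr1": 40000}, {"A": 50}, seed=4)
        reads = [_read(fam.consensus[10:31]), _read(fam.consensus[60:84])]
        mean, _ = genome_multiplicity(reads, truth.genome)
        assert mean == pytest.approx(50, abs=1)

    def test_monotone_in_copy_number(self):
        """Adding TE copies never decreases the mean genome hit count."""
        fam = generate_te_family("retrotransposon", 120, 0, 1, 0.0, 5, family_id="A")
        reads = [_read(fam.consensus[i:i + 21]) for i in (0, 40, 80)]
        last = 0.0
        for copies in (2, 10, 30):
            truth = plant_insertions([fam], {"chr1": 30000}, {"A": copies}, seed=6)
            mean, _ = genome_multiplicity(reads, truth.genome)
            assert mean >= last
            last = mean

    def test_zero_hit_reads_counted_separately(self, random_dna):
        genome = {"chr1": random_dna(1000)}
        mean, n_zero = genome_multiplicity([_read("A" * 25)], genome)
        assert np.isnan(mean) and n_zero == 1


class TestLengthDistribution:
    def test_unanimous_major24(self):
        hists = {"d0": {24: 90, 21: 10}, "d1": {24: 45, 23: 5}}
        assert classify_length_distribution(hists) == "major24"

    def test_disagreement_is_mixed(self):
        hists = {"d0": {21: 90, 24: 10}, "d1": {24: 90, 21: 10}}
        assert classify_length_distribution(hists) == "mixed"

    def test_all_below_usable_minimum_is_low(self):
        hists = {"d0": {24: 4}, "d1": {21: 5}}
        assert classify_length_distribution(hists) == "low"

    def test_dominant_outside_20_to_24_is_other(self):
        hists = {"d0": {17: 80, 21: 20}}
        assert classify_length_distribution(hists) == "other"

    def test_20_and_22_count_toward_major21(self):
        hists = {"d0": {20: 30, 22: 30, 24: 20}}
        assert classify_length_distribution(hists) == "major21"

    def test_unusable_dataset_ignored(self):
        hists = {"d0": {21: 100}, "d1": {24: 3}}
        assert classify_length_distribution(hists) == "major21"


class TestCompareMultiplicity:
    def test_strong_separation(self):
        p = compare_multiplicity([100 + i for i in range(20)], [1 + i * 0.1 for i in range(20)])
        assert p < 1e-5

    def test_identical_samples_near_half(self, rng):
        x = list(rng.integers(1, 50, size=30).astype(float))
        p = compare_multiplicity(x, x)
        assert 0.4 < p < 0.6

    def test_swapped_direction_near_one(self):
        p = compare_multiplicity([1.0] * 20, [100.0] * 20)
        assert p > 0.99

    def test_degenerate_all_tied_warns(self):
        with pytest.warns(UserWarning):
            assert compare_multiplicity([5.0] * 5, [5.0] * 5) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_multiplicity([], [1.0])


class TestAggregateSpectrum:
    def test_fractions_sum_to_one(self, typical_locus):
        prof = build_profile("h", typical_locus["reads"], typical_locus["locus"])
        df = aggregate_length_spectrum([prof])
        assert np.allclose(df.sum(axis=1), 1.0, atol=1e-9)

    def test_two_equal_lengths_split_evenly(self, random_dna):
        hp = random_dna(120)
        reads = [_read(hp[0:21], 50.0), _read(hp[30:54], 50.0)]
        prof = build_profile("h", reads, hp)
        df = aggregate_length_spectrum([prof])
        assert df.loc["d0", 21] == pytest.approx(0.5)
        assert df.loc["d0", 24] == pytest.approx(0.5)

    def test_cohort_matches_generator_weights(self, random_dna):
        """A 60% 24-nt cohort aggregates to ~0.60 24-nt fraction."""
        profiles = []
        for i in range(10):
            locus = random_dna(250)
            spec = SrnaProfileSpec(strand_category="plus_only", excision="smeared",
                                   length_weights={24: 0.6, 21: 0.4})
            table = simulate_srna_reads(locus, spec, 2000, 1, seed=100 + i)
            from temir.profiling import reads_from_table

            profiles.append(build_profile(f"h{i}", reads_from_table(table), locus))
        df = aggregate_length_spectrum(profiles)
        assert df.loc["ds0", 24] == pytest.approx(0.60, abs=0.03)


def test_build_profile_assembles_consistent_fields(typical_locus):
    genome = {"chr1": typical_locus["locus"]}
    prof = build_profile("h", typical_locus["reads"], typical_locus["locus"], genome)
    assert prof.strand_category == "plus_only"
    assert prof.mean_genome_hits >= 1.0
    assert prof.length_type in {"major21", "major24", "mixed", "low", "other"}
    assert all(p.strand == "+" for p in prof.placements)
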