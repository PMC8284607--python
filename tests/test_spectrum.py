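import numpy as np
import pytest

from mutacc.genome_io import Genome, MutationRecord, annotation_from_intervals
from mutacc.simulate import simulate_mutations
from mutacc.spectrum import (
    CHANNELS_96,
    SUBSTITUTION_TYPES,
    Spectrum96,
    aggregate_cohort_spectrum,
    build_spectrum,
    classify_substitution,
    pole_discriminator,
    region_distribution,
    six_type_percentages,
)

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp_record(rec: MutationRecord, genome: Genome) -> MutationRecord:
    length = genome.length(rec.contig)
    return MutationRecord(
        rec.contig,
        length - rec.pos + 1,
        rec.ref.translate(_COMP),
        rec.alt.translate(_COMP),
        rec.sample,
    )


class TestClassify:
    def test_pyrimidine_reference_read_directly(self):
        g = Genome({"c1": "ATCTA"})
        assert classify_substitution(MutationRecord("c1", 3, "C", "A"), g) == "T[C>A]T"

    def test_purine_reference_mapped_to_opposite_strand(self):
        g = Genome({"c1": "AGAGA"})
        assert classify_substitution(MutationRecord("c1", 3, "A", "C"), g) == "C[T>G]C"

    def test_contig_edge_gives_no_context(self):
        g = Genome({"c1": "CA"})
        assert classify_substitution(MutationRecord("c1", 1, "C", "T"), g) is None

    def test_n_in_window_gives_no_context(self):
        g = Genome({"c1": "ANCTA"})
        assert classify_substitution(MutationRecord("c1", 3, "C", "T"), g) is None


class TestBuildSpectrum:
    def test_counts_and_normalization(self):
        g = Genome({"c1": "ATCTA"})
        recs = [MutationRecord("c1", 3, "C", "A", f"s{i}") for i in range(10)]
        counts = build_spectrum(recs, g)
        assert counts["T[C>A]T"] == 10 and counts.values.sum() == 10
        norm = build_spectrum(recs, g, normalized=True)
        assert norm["T[C>A]T"] == 1.0

    def test_both_strand_representations_collapse_identically(self):
        # c1 = ATCTA; the C>A at pos 3 seen from the other strand is the
        # reverse-complement genome with a G>T at the mirrored position.
        g = Genome({"c1": "ATCTA"})
        fwd = [MutationRecord("c1", 3, "C", "A")]
        g_rc = g.reverse_complement()
        rev = [_revcomp_record(fwd[0], g)]
        assert np.array_equal(
            build_spectrum(fwd, g).values, build_spectrum(rev, g_rc).values
        )

    def test_strand_symmetry_on_simulated_data(self, at_rich_genome):
        recs = simulate_mutations(at_rich_genome, np.full(96, 1 / 96), 500, seed=5)
        flipped = [_revcomp_record(r, at_rich_genome) for r in recs]
        a = build_spectrum(recs, at_rich_genome)
        b = build_spectrum(flipped, at_rich_genome.reverse_complement())
        assert np.array_equal(a.values, b.values)

    def test_record_order_never_matters(self, at_rich_genome):
        recs = simulate_mutations(at_rich_genome, np.full(96, 1 / 96), 200, seed=6)
        a = build_spectrum(recs, at_rich_genome)
        b = build_spectrum(recs[::-1], at_rich_genome)
        assert np.array_equal(a.values, b.values)

    def test_normalized_with_no_classifiable_records_errors(self):
        g = Genome({"c1": "CA"})
        with pytest.raises(ValueError, match="classifiable"):
            build_spectrum([MutationRecord("c1", 1, "C", "T")], g, normalized=True)

    def test_simulated_signature_recovered_channelwise(self, at_rich_genome):
        rng = np.random.default_rng(0)
        sig = rng.dirichlet(np.full(96, 1.0))
        n = 50_000
        recs = simulate_mutations(at_rich_genome, sig, n, seed=1)
        spec = build_spectrum(recs, at_rich_genome, normalized=True)
        sigma = np.sqrt(sig * (1 - sig) / n)
        # 4 sigma: simultaneous bound over all 96 channels
        assert np.all(np.abs(spec.values - sig) < 4 * sigma + 1e-12)


class TestCohort:
    def test_identical_spectra_average_to_themselves(self):
        s = Spectrum96.from_mapping({"A[C>A]A": 1.0}, normalized=True, n_mutations=5)
        agg = aggregate_cohort_spectrum([s, s])
        assert agg["A[C>A]A"] == 1.0 and agg.n_mutations == 10

    def test_unit_vectors_average_half_half(self):
        e1 = Spectrum96.from_mapping({"A[C>A]A": 1.0}, normalized=True)
        e2 = Spectrum96.from_mapping({"T[T>G]T": 1.0}, normalized=True)
        agg = aggregate_cohort_spectrum([e1, e2])
        assert agg["A[C>A]A"] == 0.5 and agg["T[T>G]T"] == 0.5

    def test_matches_elementwise_mean_oracle(self):
        rng = np.random.default_rng(3)
        specs = [
            Spectrum96(v / v.sum(), normalized=True)
            for v in rng.random((5, 96))
        ]
        agg = aggregate_cohort_spectrum(specs)
        oracle = np.mean([s.values for s in specs], axis=0)
        assert np.allclose(agg.values, oracle / oracle.sum(), atol=1e-12)

    def test_mixing_counts_and_normalized_errors(self):
        c = Spectrum96.from_mapping({"A[C>A]A": 3}, normalized=False)
        n = Spectrum96.from_mapping({"A[C>A]A": 1.0}, normalized=True)
        with pytest.raises(ValueError):
            aggregate_cohort_spectrum([c, n])


class TestSixTypes:
    def test_pure_type_is_100_percent(self):
        s = Spectrum96.from_mapping({"T[C>A]T": 7}, normalized=False)
        six = six_type_percentages(s)
        assert six["C>A"] == 100.0
        assert all(six[t] == 0 for t in SUBSTITUTION_TYPES if t != "C>A")

    def test_uniform_spectrum_splits_evenly(self):
        six = six_type_percentages(Spectrum96(np.full(96, 1 / 96), normalized=True))
        for t in SUBSTITUTION_TYPES:
            assert six[t] == pytest.approx(100 / 6)

    def test_all_zero_spectrum_errors(self):
        with pytest.raises(ValueError):
            six_type_percentages(Spectrum96(np.zeros(96), normalized=False))

    def test_marginals_match_direct_tally(self, at_rich_genome):
        recs = simulate_mutations(at_rich_genome, np.full(96, 1 / 96), 1000, seed=9)
        six = six_type_percentages(build_spectrum(recs, at_rich_genome))
        # brute-force: tally substitution types straight from the records
        comp = str.maketrans("ACGT", "TGCA")
        tally = dict.fromkeys(SUBSTITUTION_TYPES, 0)
        for r in recs:
            ref, alt = r.ref, r.alt
            if ref in "AG":
                ref, alt = ref.translate(comp), alt.translate(comp)
            tally[f"{ref}>{alt}"] += 1
        n = sum(tally.values())
        for t in SUBSTITUTION_TYPES:
            assert six[t] == pytest.approx(100 * tally[t] / n)


class TestPoleDiscriminator:
    @pytest.mark.parametrize(
        "ca,tg,cg,expected",
        [
            (33.0, 15.0, 0.0, True),    # the hypermutator strain's values
            (19.9, 10.0, 0.0, False),   # C>A just under threshold
            (20.0, 4.0, 0.6, True),     # inclusive boundaries as printed
            (25.0, 3.9, 0.0, False),    # T>G under threshold
            (25.0, 10.0, 0.7, False),   # C>G above ceiling
        ],
    )
    def test_truth_table(self, ca, tg, cg, expected):
        rest = 100 - ca - tg - cg
        spec = Spectrum96.from_mapping(
            {"A[C>A]A": ca, "A[T>G]A": tg, "A[C>G]A": cg, "A[C>T]A": rest},
            normalized=False,
        )
        verdict, report = pole_discriminator(six_type_percentages(spec))
        assert verdict is expected
        assert {r["type"] for r in report} == {"C>A", "T>G", "C>G"}
        assert all(isinstance(r["passed"], bool) for r in report)


class TestRegionDistribution:
    def test_all_in_cds_against_half_cds_genome(self):
        g = Genome({"c1": "A" * 1000})
        ann = annotation_from_intervals([("c1", 1, 500, "CDS")], g)
        recs = [MutationRecord("c1", i, "A", "G") for i in range(1, 11)]
        dist = region_distribution(recs, ann)
        assert dist.observed_pct == {"CDS": 100.0}
        assert dist.expected_pct == {"CDS": 50.0, "intergenic": 50.0}

    def test_uniform_records_match_expectation(self):
        rng = np.random.default_rng(12)
        g = Genome({"c1": "A" * 10_000})
        ann = annotation_from_intervals([("c1", 1, 4000, "CDS")], g)
        n = 2000
        recs = [MutationRecord("c1", int(p), "A", "G")
                for p in rng.integers(1, 10_001, size=n)]
        dist = region_distribution(recs, ann)
        for cls, frac in (("CDS", 0.4), ("intergenic", 0.6)):
            sigma = 100 * np.sqrt(frac * (1 - frac) / n)
            assert abs(dist.observed_pct[cls] - 100 * frac) < 3 * sigma

    def test_zero_records_errors(self):
        g = Genome({"c1": "AAAA"})
        ann = annotation_from_intervals([], g)
        with pytest.raises(ValueError):
            region_distribution([], ann)

    def test_unannotated_contig_errors(self):
        g = Genome({"c1": "AAAA"})
        ann = annotation_from_intervals([], g)
        with pytest.raises(ValueError, match="unannotated"):
            region_distribution([MutationRecord("cX", 1, "A", "G")], ann)
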