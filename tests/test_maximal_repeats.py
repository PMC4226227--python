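import numpy as np
import pytest

from repeatmap import (
    Genome,
    build_index,
    enumerate_maximal_repeats,
    independent_repeat_filter,
    interpolate_counts_loglog,
    kmer_copy_histogram,
    upper_bound_spectrum,
)
from repeatmap.maximal_repeats import _lcp_array, _suffix_array
from conftest import random_genome
from oracles import brute_maximal_repeats


def _naive_sa(codes):
    return sorted(range(len(codes)), key=lambda i: tuple(codes[i:]))


class TestIndex:
    def test_suffix_order_matches_naive_sort(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 150))
            codes = rng.integers(0, 4, n).astype(np.int64)
            assert _suffix_array(codes).tolist() == _naive_sa(codes)

    def test_lcp_matches_naive(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(2, 120))
            codes = rng.integers(0, 3, n).astype(np.int64)
            sa = _suffix_array(codes)
            lcp = _lcp_array(codes, sa)
            for i in range(1, n):
                a, b = codes[sa[i - 1]:], codes[sa[i]:]
                m = 0
                while m < min(a.size, b.size) and a[m] == b[m]:
                    m += 1
                assert lcp[i] == m

    def test_toy_index_shape(self, toy):
        idx = build_index(toy)
        assert len(idx) == 2 * 16 + 2  # forward + revcomp + two sentinels
        assert sorted(idx.sa.tolist()) == list(range(len(idx)))

    def test_forward_only_mode(self, toy):
        idx = build_index(toy, include_revcomp=False)
        assert len(idx) == 17
        assert not idx.include_revcomp

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            build_index(Genome([]))

    def test_no_repeat_spans_contigs_or_ns(self):
        # 'ACGTACGT' split across contigs shares no window; N splits likewise
        g = Genome.from_dict({"a": "AAACGT", "b": "ACGTTT"})
        recs = enumerate_maximal_repeats(build_index(g), min_len=4)
        units = {r.unit for r in recs}
        assert "ACGT" in units  # repeat across contigs at distinct loci is fine
        gn = Genome.from_dict({"a": "AAACGTNACGTTT"})
        recs_n = enumerate_maximal_repeats(build_index(gn), min_len=4)
        assert all("N" not in r.unit for r in recs_n)


class TestEnumeration:
    def test_toy_maximal_tetramer_and_trimer(self, toy):
        recs = enumerate_maximal_repeats(build_index(toy), min_len=3)
        by_unit = {r.unit: r for r in recs}
        assert by_unit["ATCC"].D == 4 and by_unit["ATCC"].C == 2
        assert by_unit["ATC"].D == 3 and by_unit["ATC"].C == 3
        # tcc extends to atcc in all copies, hence is not maximal
        assert "GGA" not in by_unit  # canonical spelling of tcc

    def test_toy_dimers_count_both_strands(self, toy):
        recs = enumerate_maximal_repeats(build_index(toy), min_len=2)
        by_unit = {r.unit: r for r in recs}
        assert by_unit["AT"].C == 4
        # tc canonicalizes to ga; the forward 'ga' locus joins as a
        # reverse-strand occurrence, giving four loci in total
        assert by_unit["GA"].C == 4

    def test_occurrences_spell_unit_or_revcomp(self, toy):
        from repeatmap import reverse_complement

        for r in enumerate_maximal_repeats(build_index(toy), min_len=2):
            for iv in r.occurrences:
                s = toy[iv.contig].residues[iv.start:iv.end]
                assert s in (r.unit, reverse_complement(r.unit))

    @pytest.mark.parametrize("alphabet", ["ACGT", "AC"])
    def test_matches_brute_force_on_random_sequences(self, alphabet):
        rng = np.random.default_rng(13)
        for _ in range(15):
            g = random_genome(rng, int(rng.integers(30, 200)), alphabet)
            recs = enumerate_maximal_repeats(build_index(g), min_len=2)
            got = {r.unit: {(iv.contig, iv.start, iv.end) for iv in r.occurrences}
                   for r in recs}
            assert got == brute_maximal_repeats(g, min_len=2)

    def test_strand_invariance_of_repeat_set(self):
        from repeatmap import reverse_complement

        rng = np.random.default_rng(17)
        g = random_genome(rng, 150, alphabet="ACG")
        g_rc = Genome.from_dict({"r": reverse_complement(g["r"].residues)})
        as_set = lambda recs: {(r.unit, r.D, r.C) for r in recs}
        assert as_set(enumerate_maximal_repeats(build_index(g), min_len=2)) == as_set(
            enumerate_maximal_repeats(build_index(g_rc), min_len=2)
        )


class TestIndependentFilter:
    def test_toy_keeps_atc_drops_nothing_above(self, toy):
        recs = enumerate_maximal_repeats(build_index(toy), min_len=3)
        kept = {r.unit for r in independent_repeat_filter(recs)}
        assert kept == {"ATCC", "ATC"}

    def test_toy_dimers_at_tc_kept_aa_cc_dropped(self, toy):
        recs = enumerate_maximal_repeats(build_index(toy), min_len=2)
        kept = {r.unit: r.C for r in independent_repeat_filter(recs, non_overlap=True)}
        assert kept == {"ATCC": 2, "ATC": 3, "AT": 4, "GA": 4}

    def test_overlapping_aa_survives_without_nonoverlap_rule(self, toy):
        recs = enumerate_maximal_repeats(build_index(toy), min_len=2)
        kept = {r.unit for r in independent_repeat_filter(recs, non_overlap=False)}
        assert "AA" in kept

    def test_single_record_unchanged(self, toy):
        recs = enumerate_maximal_repeats(build_index(toy), min_len=4)
        assert independent_repeat_filter(recs) == recs


class TestUpperBound:
    def test_toy_bound_at_4_is_exact(self, toy):
        hists = [kmer_copy_histogram(toy, k) for k in (4, 5)]
        spectrum = upper_bound_spectrum(hists)
        assert spectrum.counts == {4: 1}
        assert spectrum.flavor == "upper-bound"

    def test_toy_bound_at_3_dominates_truth(self, toy):
        hists = [kmer_copy_histogram(toy, k) for k in (3, 4)]
        assert upper_bound_spectrum(hists).counts == {3: 3}  # >= 1 true trimer

    def test_bound_equals_nk_when_no_longer_repeats(self, toy):
        hists = [kmer_copy_histogram(toy, k) for k in (5, 6)]
        assert upper_bound_spectrum(hists).counts == {5: 0}

    def test_non_consecutive_lengths_rejected(self, toy):
        with pytest.raises(ValueError):
            upper_bound_spectrum([kmer_copy_histogram(toy, 3), kmer_copy_histogram(toy, 5)])

    def test_bound_dominates_independent_count_on_simulated_genome(self):
        from repeatmap import SimulationConfig, simulate_genome

        cfg = SimulationConfig(
            genome_length=30_000, n_repeat_families=8,
            repeat_length_range=(30, 120), copy_range=(2, 4),
            gap_fraction=0.0, seed=5,
        )
        g, _ = simulate_genome(cfg)
        recs = independent_repeat_filter(
            enumerate_maximal_repeats(build_index(g), min_len=20)
        )
        true_counts = {}
        for r in recs:
            true_counts[r.D] = true_counts.get(r.D, 0) + 1
        for d in sorted(true_counts):
            hists = [kmer_copy_histogram(g, k) for k in (d, d + 1)]
            bound = upper_bound_spectrum(hists).counts[d]
            assert true_counts[d] <= bound


class TestLogLogInterpolation:
    def test_decade_midpoint(self):
        assert interpolate_counts_loglog([(10, 100), (1000, 1)], [100])[100] == pytest.approx(10.0)

    def test_passes_through_knots(self):
        pts = [(10, 100.0), (50, 7.5), (1000, 1.0)]
        out = interpolate_counts_loglog(pts, [50])
        assert out[50] == pytest.approx(7.5)

    def test_exact_on_power_law_table(self):
        xs = [1, 2, 5, 10, 50, 100, 500]
        pts = [(x, x ** -2.0) for x in xs]
        queries = [3, 7, 30, 80, 300, 700]  # 700 exercises extrapolation
        out = interpolate_counts_loglog(pts, queries)
        for q in queries:
            assert out[q] == pytest.approx(q ** -2.0, rel=1e-12)

    @pytest.mark.parametrize("bad", [[(10, 100)], [(10, 0.0), (20, 1.0)], [(10, 1), (5, 2)]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            interpolate_counts_loglog(bad, [15])
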