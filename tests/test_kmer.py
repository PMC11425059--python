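"""K-mer counting, heterozygous pair detection, smudge assignment, and the
auto/allo verdict."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from ploidyscape import kmer
from ploidyscape.kmer import (InsufficientDataError, KmerHistogram,
                              KmerPairRecord, assign_smudges, canonical,
                              classify_polyploidy_mode, count_kmers,
                              estimate_genome_size, estimate_haploid_coverage,
                              find_het_pairs, reverse_complement)
from ploidyscape.polysim import simulate_kmer_pairs, simulate_polyploid_reads
from ploidyscape.polysim import PolyploidGenomeConfig

dna = st.text(alphabet="ACGT", min_size=3, max_size=15)


class TestCounting:
    def test_reverse_complement_pairing(self):
        # CGT's reverse complement is ACG, so ACGT yields canonical {ACG: 2}
        _, table = count_kmers("ACGT", 3)
        assert table == {"ACG": 2}

    def test_homopolymer(self):
        _, table = count_kmers("AAAAA", 3)
        assert table == {"AAA": 3}

    def test_total_occurrences_conserved(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(1000)]
        hist, _ = count_kmers(seqs, 21)
        assert hist.total_kmers == 1000 * 80

    def test_n_containing_kmers_skipped(self):
        _, table = count_kmers("ACGNACG", 3)
        # windows touching the N are dropped
        assert sum(table.values()) == 2

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            count_kmers("ACGTACGT", 4)

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_strand_symmetry(self, seq):
        """A sequence and its reverse complement give identical tables."""
        _, t1 = count_kmers(seq, 3)
        _, t2 = count_kmers(reverse_complement(seq), 3)
        assert t1 == t2


def brute_force_pairs(table: dict, threshold: int):
    """All-vs-all Hamming-distance-1 scan with the same mutual-best rule."""
    passed = {k: c for k, c in table.items() if c >= threshold}

    def hamming1(x, y):
        return (sum(a != b for a, b in zip(x, y)) == 1
                or sum(a != b for a, b in
                       zip(x, reverse_complement(y))) == 1)

    best = {}
    for x in passed:
        cands = [(abs(passed[y] - passed[x]), y) for y in passed
                 if y != x and hamming1(x, y)]
        if cands:
            best[x] = min(cands)[1]
    out = set()
    for x, y in best.items():
        if x < y and best.get(y) == x:
            out.add((x, y))
    return out


class TestHetPairs:
    def test_single_terminal_substitution(self):
        a, b = "A" * 21, "A" * 20 + "C"
        table = {canonical(a): 30, canonical(b): 30}
        pairs = find_het_pairs(table, 14)
        assert len(pairs) == 1
        assert pairs[0].cov_major == pairs[0].cov_minor == 30

    def test_threshold_removes_both(self):
        a, b = "A" * 21, "A" * 20 + "C"
        table = {canonical(a): 30, canonical(b): 30}
        assert find_het_pairs(table, 40) == []

    def test_most_similar_coverage_partner_wins(self):
        # middle k-mer has two candidate partners; closer coverage wins
        k0 = "A" * 21
        k1 = "A" * 10 + "C" + "A" * 10
        k2 = "A" * 10 + "G" + "A" * 10
        table = {canonical(k0): 30, canonical(k1): 29, canonical(k2): 80}
        pairs = find_het_pairs(table, 14)
        kmers = {p.kmer_major for p in pairs} | {p.kmer_minor for p in pairs}
        assert len(pairs) == 1
        assert kmers == {canonical(k0), canonical(k1)}

    @given(st.text(alphabet="ACGT", min_size=5, max_size=15),
           st.integers(min_value=1, max_value=3))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_toy_genomes(self, genome, threshold):
        _, table = count_kmers(genome, 5) if len(genome) >= 5 else (None, {})
        pairs = find_het_pairs(table, threshold)
        got = {tuple(sorted((p.kmer_major, p.kmer_minor))) for p in pairs}
        assert got == brute_force_pairs(table, threshold)

    def test_planted_diploid_sites_recovered(self):
        cfg = PolyploidGenomeConfig(
            ploidy_max=2, genotype_mixture={"AB": 1.0}, haploid_coverage=30.0,
            genome_len=30_000, k=21, seed=1)
        reads, truth = simulate_polyploid_reads(cfg)
        _, table = count_kmers(reads, 21)
        pairs = find_het_pairs(table, 14)
        paired = {p.kmer_major for p in pairs} | {p.kmer_minor for p in pairs}
        # a planted site is recovered when its centred allele k-mers (from
        # the truth table) participate in a detected pair
        recovered = truth.apply(
            lambda rec: rec["kmer_a"] in paired and rec["kmer_b"] in paired,
            axis=1)
        assert recovered.mean() >= 0.95


class TestCoverageEstimate:
    def test_pure_diploid_row(self):
        df = pd.DataFrame({"cov_major": [30] * 200, "cov_minor": [30] * 200})
        assert estimate_haploid_coverage(df, 8) == pytest.approx(30, rel=0.02)

    def test_pure_aaab_row_prefers_quarter_ratio(self):
        """Sum 120 with minor fraction 0.25 anchors c at 30, not 60 or 40."""
        df = simulate_kmer_pairs({"AAAB": 1.0}, 30.0, 2000, seed=2)
        assert estimate_haploid_coverage(df, 4) == pytest.approx(30, rel=0.05)

    def test_two_row_mixture_prefers_parsimonious_coverage(self):
        df = simulate_kmer_pairs({"AB": 0.5, "AABB": 0.5}, 30.0, 4000, seed=3)
        assert estimate_haploid_coverage(df, 8) == pytest.approx(30, rel=0.05)

    def test_too_few_pairs_signals_insufficient_data(self):
        df = pd.DataFrame({"cov_major": [30] * 50, "cov_minor": [30] * 50})
        with pytest.raises(InsufficientDataError):
            estimate_haploid_coverage(df)


class TestAssignment:
    def test_exact_centres(self):
        df = pd.DataFrame({"cov_major": [30, 90], "cov_minor": [30, 30]})
        comp = assign_smudges(df, 30.0, 8)
        assert list(comp.assignments["genotype_class"]) == ["AB", "AAAB"]

    def test_conservation_with_repeat_exclusion(self):
        df = pd.DataFrame({"cov_major": [30] * 99 + [2000],
                           "cov_minor": [30] * 99 + [1500]})
        comp = assign_smudges(df, 30.0, 8)
        assert comp.n_excluded == 1
        assert comp.n_pairs_used + comp.n_excluded == 100

    def test_proportions_sum_to_one(self):
        df = simulate_kmer_pairs({"AB": 0.3, "AABB": 0.7}, 25.0, 2000, seed=4)
        comp = assign_smudges(df, 25.0, 8)
        assert sum(comp.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_row_order_invariance(self):
        df = simulate_kmer_pairs({"AB": 0.5, "AAAB": 0.5}, 25.0, 1000, seed=5)
        comp1 = assign_smudges(df, 25.0, 8)
        comp2 = assign_smudges(df.iloc[::-1].reset_index(drop=True), 25.0, 8)
        for k in comp1.proportions:
            assert comp1.proportions[k] == pytest.approx(
                comp2.proportions[k], abs=1e-9)

    def test_record_validation(self):
        with pytest.raises(ValueError):
            KmerPairRecord(None, None, 10, 20)

    def test_monotone_rediploidization_index(self):
        """Raising the share of diverged (AABB-like) duplicate loci raises
        the rediploidization index monotonically."""
        idx = []
        fractions = [0.1, 0.3, 0.5, 0.7, 0.9]
        for i, f in enumerate(fractions):
            mix = {"AAAB": (1 - f) * 0.8, "AABB": f * 0.8, "AB": 0.2}
            df = simulate_kmer_pairs(mix, 25.0, 4000, seed=10 + i)
            comp = assign_smudges(df, 25.0, 4)
            v = classify_polyploidy_mode(comp)
            idx.append(v.rediploidization_index)
        rho = spearmanr(fractions, idx).statistic
        assert rho > 0.9


class TestVerdict:
    def test_allotetraploid_profile(self):
        """AB-dominated composition (the common-carp pattern) reads allo."""
        comp = kmer.PloidyComposition(
            proportions={"AB": 0.59, "AABB": 0.30, "AAAB": 0.03,
                         "AAB": 0.08},
            haploid_coverage_estimate=25.0, n_pairs_used=1000)
        assert classify_polyploidy_mode(comp).mode == "allo"

    def test_autotetraploid_profile(self):
        """AAAB-dominated composition (the alfalfa pattern) reads auto."""
        comp = kmer.PloidyComposition(
            proportions={"AAAB": 0.63, "AABB": 0.15, "AB": 0.12,
                         "AAB": 0.10},
            haploid_coverage_estimate=25.0, n_pairs_used=1000)
        verdict = classify_polyploidy_mode(comp)
        assert verdict.mode == "auto"
        assert verdict.auto_score >= 0.63

    def test_pure_diploid_is_ambiguous(self):
        comp = kmer.PloidyComposition(
            proportions={"AB": 1.0}, haploid_coverage_estimate=25.0,
            n_pairs_used=1000)
        assert classify_polyploidy_mode(comp).mode == "ambiguous"


class TestGenomeSize:
    def test_point_histogram(self):
        hist = KmerHistogram(k=21, counts={30: 10 ** 8})
        assert estimate_genome_size(hist) == pytest.approx(1e8)

    def test_error_spike_excluded(self):
        clean = KmerHistogram(k=21, counts={29: 40, 30: 100, 31: 42})
        spiked = KmerHistogram(k=21, counts={1: 10 ** 6, 2: 10, 29: 40,
                                             30: 100, 31: 42})
        clean_size = estimate_genome_size(clean)
        # same modal depth; the spike only adds its own occurrences
        assert estimate_genome_size(spiked) == pytest.approx(
            clean_size + (10 ** 6 + 20) / 30)

    def test_monotone_histogram_rejected(self):
        hist = KmerHistogram(k=21, counts={1: 100, 2: 50, 3: 10})
        with pytest.raises(InsufficientDataError):
            estimate_genome_size(hist)

    def test_simulated_diploid_within_five_percent(self):
        cfg = PolyploidGenomeConfig(
            ploidy_max=2, genotype_mixture={"AB": 1.0}, haploid_coverage=20.0,
            genome_len=1_000_000, het_density=0.0005, k=21, seed=6)
        reads, _ = simulate_polyploid_reads(cfg)
        hist, _ = count_kmers(reads, 21)
        est = estimate_genome_size(hist)
        assert est == pytest.approx(1_000_000, rel=0.05)
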