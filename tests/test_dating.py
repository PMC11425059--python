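"""NG86 Ka/Ks, Ks mixtures, proportional dating, escape times, supermatrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ng86_oracle
from ploidyscape import dating
from ploidyscape.codon import SENSE_CODONS
from ploidyscape.dating import (CalibratedEvent, NoDataError,
                                export_supermatrix, family_ks, fit_ks_mixture,
                                ng86_kaks, proportional_date,
                                pseudogene_escape_time,
                                read_supermatrix_phylip, substitution_rate,
                                write_supermatrix_phylip)

codon_seq = st.lists(st.sampled_from(SENSE_CODONS), min_size=3,
                     max_size=12).map("".join)


class TestNg86:
    def test_identical_sequences_give_zero(self):
        seq = "ATGGCTAAA" * 5
        est = ng86_kaks(seq, seq)
        assert est.ka == 0.0 and est.ks == 0.0

    def test_pure_synonymous_change(self):
        # glycine GGT -> GGC is synonymous at the third position
        a, b = "GGT" * 100, "GGC" + "GGT" * 99
        est = ng86_kaks(a, b)
        assert est.ks > 0 and est.ka == 0.0

    def test_symmetry_is_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(SENSE_CODONS, 20))
            b = "".join(rng.choice(SENSE_CODONS, 20))
            e1, e2 = ng86_kaks(a, b), ng86_kaks(b, a)
            assert (e1.syn_sites, e1.nonsyn_sites, e1.syn_diffs,
                    e1.nonsyn_diffs) == (e2.syn_sites, e2.nonsyn_sites,
                                         e2.syn_diffs, e2.nonsyn_diffs)

    @given(codon_seq, codon_seq)
    @settings(max_examples=40, deadline=None)
    def test_site_conservation(self, a, b):
        n = min(len(a), len(b)) // 3 * 3
        a, b = a[:n], b[:n]
        try:
            est = ng86_kaks(a, b)
        except NoDataError:
            return
        assert est.syn_sites + est.nonsyn_sites == pytest.approx(
            3 * est.n_codons)

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            base = rng.choice(SENSE_CODONS, 30)
            other = base.copy()
            for j in rng.choice(30, size=3, replace=False):
                other[j] = rng.choice(SENSE_CODONS)
            a, b = "".join(base), "".join(other)
            est = ng86_kaks(a, b)
            S, N, Sd, Nd = ng86_oracle(a, b)
            assert est.syn_sites == pytest.approx(S)
            assert est.nonsyn_sites == pytest.approx(N)
            assert est.syn_diffs == pytest.approx(Sd)
            assert est.nonsyn_diffs == pytest.approx(Nd)

    def test_saturation_flagged(self):
        a = "TTT" * 30
        b = "GGG" * 30
        est = ng86_kaks(a, b)
        assert est.saturated and est.ka is None

    def test_gap_only_overlap_is_no_data(self):
        with pytest.raises(NoDataError):
            ng86_kaks("---", "ATG")


class TestFamilyKs:
    def test_identical_s_copies_give_zero_node(self):
        seqs = {"S1": "ATGGCT" * 20, "S2": "ATGGCT" * 20,
                "R1": "ATGGCT" * 20, "R2": "ATGGCC" * 20,
                "P1": "ATGGCT" * 20, "P2": "ATGGCT" * 20}
        fk = family_ks(seqs, "fam")
        assert fk.s_pair_ks == 0.0

    def test_saturated_pair_excluded_and_counted(self):
        seqs = {"S1": "TTT" * 30, "S2": "GGG" * 30,
                "R1": "ATGGCT" * 15, "R2": "ATGGCT" * 15,
                "P1": "ATGGCT" * 15, "P2": "ATGGCC" + "ATGGCT" * 14}
        fk = family_ks(seqs, "fam")
        assert fk.n_saturated == 1
        assert fk.pair_ks["S1-S2"] is None
        assert fk.dup_node_ks is not None


class TestMixture:
    def test_too_few_values_rejected(self):
        with pytest.raises(NoDataError):
            fit_ks_mixture([0.1] * 19)

    def test_degenerate_input_single_component(self):
        dist = fit_ks_mixture([0.1] * 25)
        assert dist.n_components == 1
        assert dist.variances_log[0] == 0.0

    def test_two_separated_peaks_recovered(self):
        """Modes planted at the two WGD Ks scales (0.022 and 0.132)."""
        rng = np.random.default_rng(1)
        vals = np.concatenate([
            np.exp(rng.normal(np.log(0.022), 0.25, 200)),
            np.exp(rng.normal(np.log(0.132), 0.25, 200))])
        dist = fit_ks_mixture(vals, max_components=4, seed=0)
        assert dist.n_components == 2
        modes = np.sort(dist.component_modes)
        assert modes[0] == pytest.approx(0.022, rel=0.2)
        assert modes[1] == pytest.approx(0.132, rel=0.2)

    def test_single_lognormal_prefers_one_component(self):
        wins = 0
        for s in range(40):
            rng = np.random.default_rng(100 + s)
            vals = np.exp(rng.normal(np.log(0.1), 0.3, 150))
            dist = fit_ks_mixture(vals, max_components=3, seed=0)
            wins += dist.n_components == 1
        assert wins / 40 >= 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        vals = np.exp(rng.normal(-2.0, 0.4, 120))
        d1 = fit_ks_mixture(vals, seed=3)
        d2 = fit_ks_mixture(vals, seed=3)
        assert np.array_equal(d1.means_log, d2.means_log)
        assert d1.n_components == d2.n_components


class TestDating:
    REF = CalibratedEvent("shared_wgd", 210.7, 0.132)

    def test_proportional_scaling(self):
        assert proportional_date(0.022, self.REF) == pytest.approx(35.12,
                                                                   abs=0.005)
        assert proportional_date(self.REF.ks, self.REF) == 210.7
        assert proportional_date(0.066, self.REF) == pytest.approx(105.35,
                                                                   abs=0.005)

    def test_linearity(self):
        a = proportional_date(0.01, self.REF)
        assert proportional_date(0.03, self.REF) == pytest.approx(3 * a)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            proportional_date(-0.1, self.REF)

    @pytest.mark.parametrize("ks,rate", [
        (0.132, 3.13e-10), (0.121, 2.87e-10), (0.151, 3.58e-10)])
    def test_absolute_rates(self, ks, rate):
        assert substitution_rate(ks, 210.7e6) == pytest.approx(rate,
                                                               abs=0.005e-10)

    def test_rate_halves_when_time_doubles(self):
        assert substitution_rate(0.1, 2e8) == \
            pytest.approx(substitution_rate(0.1, 1e8) / 2)

    def test_zero_ks_rate(self):
        assert substitution_rate(0.0, 1e8) == 0.0

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            substitution_rate(0.1, 0.0)


class TestEscape:
    def test_functional_ratio_means_never_escaped(self):
        est = pseudogene_escape_time(0.02, 0.1, 0.2, 100.0)
        assert est.t_escape == 0.0

    def test_neutral_ratio_means_escaped_at_start(self):
        est = pseudogene_escape_time(0.1, 0.1, 0.2, 100.0)
        assert est.t_escape == pytest.approx(100.0)

    def test_linear_interpolation(self):
        # ratio halfway between omega and 1 -> escape at half the span
        est = pseudogene_escape_time(0.06, 0.1, 0.2, 100.0)
        assert est.t_escape == pytest.approx(50.0)

    def test_super_neutral_ratio_flagged(self):
        est = pseudogene_escape_time(0.2, 0.1, 0.2, 100.0,
                                     neutral_tolerance=0.25)
        assert est.exceeds_neutral and est.clipped
        assert est.t_escape == 100.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pseudogene_escape_time(0.1, 0.0, 0.2, 100.0)
        with pytest.raises(ValueError):
            pseudogene_escape_time(0.1, 0.1, 1.5, 100.0)


class TestSupermatrix:
    def test_concatenation_and_partitions(self):
        taxa = ["P1", "P2", "S1", "S2", "R1", "R2", "L1"]
        f1 = ("famA", {t: "A" * 300 for t in taxa})
        f2 = ("famB", {t: "C" * 150 for t in taxa})
        sm = export_supermatrix([f1, f2])
        assert sm.length == 450
        assert sm.partitions == [("famA", 1, 300), ("famB", 301, 450)]

    def test_empty_input_rejected(self):
        with pytest.raises(NoDataError):
            export_supermatrix([])

    def test_length_mismatch_names_family(self):
        taxa = ["S1", "S2"]
        bad = ("famX", {"S1": "AAA", "S2": "AAAAAA"})
        with pytest.raises(ValueError, match="famX"):
            export_supermatrix([("ok", {t: "AAA" for t in taxa}), bad])

    def test_phylip_round_trip(self, tmp_path):
        taxa = ["P1", "P2", "S1", "S2", "R1", "R2", "L1"]
        sm = export_supermatrix([("famA", {t: "ACGTAA" for t in taxa})])
        path = tmp_path / "sm.phy"
        write_supermatrix_phylip(sm, path)
        back = read_supermatrix_phylip(path)
        assert back.sequences == sm.sequences
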