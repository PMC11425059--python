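"""Rooting, LORe/AORe topology classification, and chromosome enrichment."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from ploidyscape.trees import (MalformedFamilyError, NoSignalError,
                               TopologyLabel, chrom_distribution,
                               classify_topology, root_with_outgroup,
                               summarize_proportions)


class TestRooting:
    def test_roots_on_outgroup_and_drops_it(self):
        t = root_with_outgroup("((S1,R1),((S2,R2),(P1,P2)),L1);")
        leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
        assert leaves == {"S1", "S2", "R1", "R2", "P1", "P2"}
        assert classify_topology(t).label == "PP_SR_SR"

    def test_missing_outgroup_rejected(self):
        with pytest.raises(MalformedFamilyError):
            root_with_outgroup("((S1,R1),((S2,R2),(P1,P2)));")

    def test_duplicate_outgroup_rejected(self):
        with pytest.raises(MalformedFamilyError):
            root_with_outgroup("((S1,R1),(L1,L1),(S2,(R2,(P1,P2))));")

    def test_reroot_unroot_round_trip_preserves_topology(self):
        """Rerooting on L1 then unrooting recovers the original unrooted
        topology (Robinson-Foulds distance 0)."""
        rng = np.random.default_rng(0)
        labels = ["P1", "P2", "S1", "S2", "R1", "R2", "L1"]
        for rep in range(20):
            order = list(rng.permutation(labels))
            # random rooted shape by sequential attachment
            newick = order[0]
            for leaf in order[1:]:
                if rng.random() < 0.5:
                    newick = f"({newick},{leaf})"
                else:
                    newick = f"({leaf},{newick})"
            newick += ";"
            taxa = dendropy.TaxonNamespace()
            orig = dendropy.Tree.get(data=newick, schema="newick",
                                     taxon_namespace=taxa)
            rooted = root_with_outgroup(newick)
            back = dendropy.Tree.get(
                data=rooted.as_string(schema="newick").replace("[&R] ", ""),
                schema="newick", taxon_namespace=taxa)
            orig.prune_taxa_with_labels(["L1"])
            orig.encode_bipartitions()
            back.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(
                orig, back, is_bipartitions_updated=True)
            assert rf == 0


class TestClassification:
    @pytest.mark.parametrize("newick,label,cls", [
        ("((P1,(S1,R1)),(P2,(S2,R2)));", "PSR_PSR", "AORe"),
        ("((P1,(S2,R1)),(P2,(S1,R2)));", "PSR_PSR", "AORe"),
        ("((P1,P2),((S1,R1),(S2,R2)));", "PP_SR_SR", "LORe"),
        ("((P1,P2),((S1,S2),(R1,R2)));", "PP_SS_RR", "LORe"),
        ("((S1,P1),((S2,P2),(R1,R2)));", "OTHER", "none"),
    ])
    def test_named_topologies(self, newick, label, cls):
        got = classify_topology(newick)
        assert (got.label, got.resolution_class) == (label, cls)

    def test_copy_index_swap_invariance(self):
        """Relabelling S1<->S2, R1<->R2, P1<->P2 never changes the class."""
        rng = np.random.default_rng(1)
        labels = ["P1", "P2", "S1", "S2", "R1", "R2"]
        swap = {"S1": "S2", "S2": "S1", "R1": "R2", "R2": "R1",
                "P1": "P2", "P2": "P1"}
        for rep in range(40):
            order = list(rng.permutation(labels))
            newick = order[0]
            for leaf in order[1:]:
                newick = (f"({newick},{leaf})" if rng.random() < 0.5
                          else f"({leaf},{newick})")
            newick += ";"
            swapped = newick
            for a, b in [("S1", "Sx"), ("S2", "S1"), ("Sx", "S2"),
                         ("R1", "Rx"), ("R2", "R1"), ("Rx", "R2"),
                         ("P1", "Px"), ("P2", "P1"), ("Px", "P2")]:
                swapped = swapped.replace(a, b)
            assert classify_topology(newick).label == \
                classify_topology(swapped).label

    def test_wrong_leaf_set_rejected(self):
        with pytest.raises(MalformedFamilyError):
            classify_topology("((P1,P2),(S1,S2));")


class TestSupportCollapse:
    TREE = "((P1,(S1,R1))90,(P2,(S2,R2))40);"

    def test_high_threshold_unresolves(self):
        # the 0.40-support edge collapses; several refinements fit
        lab = classify_topology(self.TREE, support_threshold=0.5)
        assert lab.label in ("PSR_PSR", "UNRESOLVED")

    def test_support_monotonicity(self):
        """Raising the threshold can move a named class to UNRESOLVED but
        never to a different named class."""
        previous = None
        for thr in (0.0, 0.3, 0.5, 0.95, 1.01):
            lab = classify_topology(self.TREE, support_threshold=thr).label
            if previous and previous != lab:
                assert lab == "UNRESOLVED" or previous == "UNRESOLVED"
            previous = lab


class TestSummary:
    def test_proportions_over_named_classes(self):
        labels = [TopologyLabel.of("PSR_PSR")] * 3 + \
            [TopologyLabel.of("PP_SR_SR")] + [TopologyLabel.of("OTHER")]
        s = summarize_proportions(labels)
        assert s.proportions == {"PSR_PSR": 0.75, "PP_SR_SR": 0.25,
                                 "PP_SS_RR": 0.0}
        assert s.n_other == 1

    def test_all_other_signals_no_signal(self):
        with pytest.raises(NoSignalError):
            summarize_proportions([TopologyLabel.of("OTHER")] * 4)


def _chrom_table(macro_rate, micro_rate, n_macro=6, n_micro=27,
                 fams_per_chrom=40, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_macro + n_micro):
        size = "macro" if c < n_macro else "medium_micro"
        rate = macro_rate if size == "macro" else micro_rate
        for i in range(fams_per_chrom):
            cls = "AORe" if rng.random() < rate else "LORe"
            rows.append((f"f{c}_{i}", cls, f"chr{c + 1}", size))
    return pd.DataFrame(rows, columns=["family_id", "resolution_class",
                                       "chromosome", "size_class"])


class TestChromDistribution:
    def test_complete_separation_is_significant(self):
        df = _chrom_table(1.0, 0.0, n_macro=3, n_micro=3)
        res = chrom_distribution(df)
        assert res.test_defined
        assert res.p_value < 0.01
        assert res.direction == "macro_enriched"

    def test_identical_fractions_give_null_result(self):
        df = _chrom_table(1.0, 1.0, n_macro=3, n_micro=3)
        res = chrom_distribution(df)
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_single_macro_chromosome_undefined(self):
        df = _chrom_table(0.8, 0.4, n_macro=1, n_micro=5)
        res = chrom_distribution(df)
        assert not res.test_defined

    def test_power_under_simulated_enrichment(self):
        """Macro AORe rate 0.8 vs micro 0.4 (6 + 27 chromosomes, 40
        families each) is detected at the 0.01 level in most replicates."""
        hits = sum(
            chrom_distribution(_chrom_table(0.8, 0.4, seed=s)).p_value < 0.01
            for s in range(200))
        assert hits / 200 >= 0.80
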