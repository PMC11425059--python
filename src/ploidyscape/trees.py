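"""Rooting and LORe/AORe classification of ohnolog quartet gene trees.

A screened family carries six ingroup copies (P1, P2, S1, S2, R1, R2) and a
single outgroup copy.  After rooting on the outgroup and removing it, the
rooted 6-leaf topology falls into one of three informative shapes:

* PSR-PSR — two clades each holding one P, one S and one R copy: the copies
  resolved before any speciation (ancestral ohnologue resolution, AORe);
* PP-SR-SR — a P-P clade plus two S-R clades: rediploidization fell between
  the two speciations (lineage-specific resolution, LORe);
* PP-SS-RR — all three within-species pairs are clades: rediploidization
  postdated the last speciation (LORe).

Classification is by clade-set membership; edges with support below a
threshold may first be collapsed, after which a tree is classified only if
exactly one definition is satisfiable on some binary refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

INGROUP_LEAVES = frozenset({"P1", "P2", "S1", "S2", "R1", "R2"})

NAMED_LABELS = ("PSR_PSR", "PP_SR_SR", "PP_SS_RR")

_RESOLUTION = {"PSR_PSR": "AORe", "PP_SR_SR": "LORe", "PP_SS_RR": "LORe",
               "OTHER": "none", "UNRESOLVED": "none"}


class MalformedFamilyError(ValueError):
    pass


class NoSignalError(ValueError):
    pass


@dataclass(frozen=True)
class TopologyLabel:
    label: str          # PSR_PSR | PP_SR_SR | PP_SS_RR | OTHER | UNRESOLVED
    resolution_class: str   # AORe | LORe | none

    @classmethod
    def of(cls, label: str) -> "TopologyLabel":
        return cls(label=label, resolution_class=_RESOLUTION[label])


def _as_tree(tree: "dendropy.Tree | str") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    try:
        return dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:   # duplicate labels, syntax errors, ...
        raise MalformedFamilyError(f"unreadable newick: {exc}") from exc


def root_with_outgroup(tree: "dendropy.Tree | str",
                       outgroup_label: str = "L1") -> dendropy.Tree:
    """Root on the outgroup edge and drop the outgroup leaf.

    Returns a rooted 6-leaf tree; ingroup branch lengths are preserved.
    """
    t = _as_tree(tree).clone(depth=1)
    og = [lf for lf in t.leaf_node_iter()
          if lf.taxon is not None and lf.taxon.label == outgroup_label]
    if len(og) != 1:
        raise MalformedFamilyError(
            f"expected exactly one {outgroup_label!r} leaf, found {len(og)}")
    t.is_rooted = True
    t.reroot_at_edge(og[0].edge, update_bipartitions=False)
    t.prune_taxa([og[0].taxon], suppress_unifurcations=True)
    leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
    if leaves != set(INGROUP_LEAVES):
        raise MalformedFamilyError(
            f"rooted tree has leaves {sorted(leaves)}; "
            f"expected {sorted(INGROUP_LEAVES)}")
    return t


def _parse_support(label: str | None) -> float | None:
    if not label:
        return None
    token = str(label).split("/")[0]
    try:
        val = float(token)
    except ValueError:
        return None
    return val / 100.0 if val > 1.0 else val


def collapse_low_support(tree: dendropy.Tree,
                         support_threshold: float) -> dendropy.Tree:
    """Collapse internal edges whose support is below the threshold."""
    t = tree.clone(depth=1)
    to_collapse = []
    for node in t.preorder_internal_node_iter(exclude_seed_node=True):
        support = _parse_support(node.label)
        if support is not None and support < support_threshold:
            to_collapse.append(node.edge)
    for edge in to_collapse:
        edge.collapse()
    return t


def _realizable_clades(tree: dendropy.Tree) -> set[frozenset]:
    """Leaf sets realizable as clades on some binary refinement.

    For each node, every union of a nonempty subset of its children's leaf
    sets is realizable; on a binary tree this is exactly the clade set.
    """
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            continue
        kid_sets = [frozenset(lf.taxon.label for lf in k.leaf_iter())
                    for k in kids]
        for r in range(1, len(kid_sets) + 1):
            for combo in combinations(kid_sets, r):
                u = frozenset().union(*combo)
                if len(u) >= 2:
                    out.add(u)
    return out


def _definitions_satisfied(clades: set[frozenset]) -> list[str]:
    satisfied = []
    # PSR_PSR: two disjoint {P,S,R} triples both clades
    psr = False
    for s_for_p1 in ("S1", "S2"):
        for r_for_p1 in ("R1", "R2"):
            t1 = frozenset({"P1", s_for_p1, r_for_p1})
            t2 = INGROUP_LEAVES - t1
            if t1 in clades and t2 in clades:
                psr = True
    if psr:
        satisfied.append("PSR_PSR")
    # PP_SR_SR: P pair is a clade; S/R leaves form two disjoint S-R duos
    pp = frozenset({"P1", "P2"}) in clades
    duo = lambda a, b: frozenset({a, b})  # noqa: E731
    sr_pairing = ((duo("S1", "R1") in clades and duo("S2", "R2") in clades)
                  or (duo("S1", "R2") in clades and duo("S2", "R1") in clades))
    if pp and sr_pairing:
        satisfied.append("PP_SR_SR")
    # PP_SS_RR: all three within-species pairs are clades
    if (pp and duo("S1", "S2") in clades and duo("R1", "R2") in clades):
        satisfied.append("PP_SS_RR")
    return satisfied


def classify_topology(tree: "dendropy.Tree | str",
                      support_threshold: float | None = None,
                      ) -> TopologyLabel:
    """Classify a rooted 6-leaf quartet gene tree.

    On a binary tree the three definitions are mutually exclusive (asserted).
    After support collapsing, a multifurcating tree is classified only when
    exactly one definition is satisfiable on some binary refinement;
    several satisfiable definitions give UNRESOLVED, none gives OTHER.
    """
    t = _as_tree(tree)
    leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
    if leaves != set(INGROUP_LEAVES):
        raise MalformedFamilyError(
            f"expected leaves {sorted(INGROUP_LEAVES)}, got {sorted(leaves)}")
    if support_threshold is not None:
        t = collapse_low_support(t, support_threshold)
    is_binary = all(len(n.child_nodes()) == 2
                    for n in t.preorder_internal_node_iter())
    satisfied = _definitions_satisfied(_realizable_clades(t))
    if is_binary:
        assert len(satisfied) <= 1, (
            "topology definitions must be mutually exclusive on binary trees")
        return TopologyLabel.of(satisfied[0] if satisfied else "OTHER")
    if len(satisfied) == 1:
        return TopologyLabel.of(satisfied[0])
    return TopologyLabel.of("UNRESOLVED" if satisfied else "OTHER")


@dataclass
class TopologySummary:
    counts: dict[str, int]
    proportions: dict[str, float]    # over the three named classes
    n_classifiable: int
    n_other: int
    n_unresolved: int


def summarize_proportions(labels) -> TopologySummary:
    """Class proportions among classifiable trees; OTHER/UNRESOLVED apart."""
    names = [lb.label if isinstance(lb, TopologyLabel) else str(lb)
             for lb in labels]
    counts = {k: names.count(k) for k in
              (*NAMED_LABELS, "OTHER", "UNRESOLVED")}
    n_class = sum(counts[k] for k in NAMED_LABELS)
    if n_class == 0:
        raise NoSignalError("no classifiable trees")
    props = {k: counts[k] / n_class for k in NAMED_LABELS}
    return TopologySummary(counts=counts, proportions=props,
                           n_classifiable=n_class, n_other=counts["OTHER"],
                           n_unresolved=counts["UNRESOLVED"])


@dataclass
class ChromDistributionResult:
    per_chromosome: pd.DataFrame
    t_stat: float | None
    p_value: float | None
    direction: str                   # macro_enriched | micro_enriched | none
    test_defined: bool
    reason: str | None = None


def chrom_distribution(table: pd.DataFrame) -> ChromDistributionResult:
    """AORe/LORe chromosome distribution with a macro-vs-micro t-test.

    ``table`` columns: family_id, resolution_class (AORe/LORe), chromosome,
    size_class (macro/medium_micro).  The test compares per-chromosome AORe
    fractions between the two size classes (two-sample Student's t).
    """
    df = table[table["resolution_class"].isin(["AORe", "LORe"])]
    if df.empty:
        raise NoSignalError("no classified families")
    rows = []
    for (chrom, size), grp in df.groupby(["chromosome", "size_class"]):
        n_a = int((grp["resolution_class"] == "AORe").sum())
        n_l = int((grp["resolution_class"] == "LORe").sum())
        rows.append((chrom, size, n_a, n_l, n_a / (n_a + n_l)))
    per_chrom = pd.DataFrame(rows, columns=[
        "chromosome", "size_class", "n_aore", "n_lore", "aore_fraction"])
    macro = per_chrom.loc[per_chrom["size_class"] == "macro",
                          "aore_fraction"].to_numpy()
    micro = per_chrom.loc[per_chrom["size_class"] == "medium_micro",
                          "aore_fraction"].to_numpy()
    if len(macro) < 2 or len(micro) < 2:
        return ChromDistributionResult(
            per_chrom, None, None, "none", False,
            reason="a size class has fewer than 2 chromosomes")
    if np.ptp(macro) == 0 and np.ptp(micro) == 0:
        # degenerate: constant fractions in both classes
        if macro[0] == micro[0]:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if macro[0] > micro[0] else -np.inf
            p = 0.0
    else:
        t_stat, p = stats.ttest_ind(macro, micro, equal_var=True)
        t_stat, p = float(t_stat), float(p)
    if macro.mean() > micro.mean():
        direction = "macro_enriched"
    elif macro.mean() < micro.mean():
        direction = "micro_enriched"
    else:
        direction = "none"
    return ChromDistributionResult(per_chrom, t_stat, p, direction, True)
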