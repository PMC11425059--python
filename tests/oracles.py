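"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own tables and tree machinery:
translation goes through Bio.Seq, trees are nested tuples classified by
explicit clade enumeration.
"""

from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_oracle(seq1: str, seq2: str):
    """(syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs) by explicit
    per-site degeneracy counting and full substitution-path enumeration."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if len(c1) < 3 or any(b not in BASES for b in c1 + c2):
            continue
        if _aa(c1) == "*" or _aa(c2) == "*":
            continue
        for codon in (c1, c2):
            for pos in range(3):
                n_syn = 0
                for b in BASES:
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1:]
                    if _aa(alt) == _aa(codon) and _aa(alt) != "*":
                        n_syn += 1
                S += n_syn / 6.0          # averaged over the two sequences
                N += (3 - n_syn) / 6.0
        diff = [p for p in range(3) if c1[p] != c2[p]]
        if not diff:
            continue
        paths = []
        for order in permutations(diff):
            cur = c1
            sd = nd = 0
            hit_stop = False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if _aa(nxt) == "*":
                    hit_stop = True
                    nd += 1
                elif _aa(nxt) == _aa(cur) and _aa(cur) != "*":
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((hit_stop, sd, nd))
        clean = [(sd, nd) for h, sd, nd in paths if not h]
        use = clean if clean else [(sd, nd) for _, sd, nd in paths]
        Sd += sum(p[0] for p in use) / len(use)
        Nd += sum(p[1] for p in use) / len(use)
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# rooted 6-leaf tree enumeration and clade-set classification


def enumerate_rooted_trees(labels):
    """All rooted binary leaf-labelled trees as nested tuples; (2n-3)!!."""
    if len(labels) == 1:
        return [labels[0]]
    first, rest = labels[0], labels[1:]
    trees = [first]
    for leaf in rest:
        trees = [t for tr in trees for t in _insert(tr, leaf)]
    return trees


def _insert(tree, leaf):
    out = [(tree, leaf)]                   # new root above everything
    if isinstance(tree, tuple):
        left, right = tree
        out.extend((t, right) for t in _insert(left, leaf))
        out.extend((left, t) for t in _insert(right, leaf))
    return out


def tuple_to_newick(tree) -> str:
    def render(t):
        if isinstance(t, tuple):
            return f"({render(t[0])},{render(t[1])})"
        return t
    return render(tree) + ";"


def _clades(tree, acc):
    if isinstance(tree, tuple):
        leaves = frozenset()
        for child in tree:
            leaves |= _clades(child, acc)
        acc.add(leaves)
        return leaves
    return frozenset({tree})


def oracle_classify(tree) -> str:
    """Clade-set classification of a rooted binary 6-leaf tuple tree."""
    acc = set()
    _clades(tree, acc)
    psr = any(
        frozenset({"P1", s, r}) in acc
        and frozenset({"P2", s2, r2}) in acc
        for s, s2 in (("S1", "S2"), ("S2", "S1"))
        for r, r2 in (("R1", "R2"), ("R2", "R1")))
    pp = frozenset({"P1", "P2"}) in acc
    sr_sr = pp and (
        (frozenset({"S1", "R1"}) in acc and frozenset({"S2", "R2"}) in acc)
        or (frozenset({"S1", "R2"}) in acc
            and frozenset({"S2", "R1"}) in acc))
    ss_rr = pp and frozenset({"S1", "S2"}) in acc \
        and frozenset({"R1", "R2"}) in acc
    matches = [name for name, hit in
               (("PSR_PSR", psr), ("PP_SR_SR", sr_sr), ("PP_SS_RR", ss_rr))
               if hit]
    assert len(matches) <= 1
    return matches[0] if matches else "OTHER"
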