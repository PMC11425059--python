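"""Alignment hygiene for quartet families: codon back-translation, a simple
conserved-block column filter, the minimum-length gate, and a neighbor-
joining fallback tree for end-to-end runs without an external tree inference.
"""

from __future__ import annotations

import io

import dendropy

GAP = "-"
MIN_ALIGNMENT_BP = 150


def back_translate(protein_alignment: dict[str, str],
                   cds: dict[str, str]) -> dict[str, str]:
    """Map a gapped protein alignment back onto its coding sequences."""
    out = {}
    for name, prot in protein_alignment.items():
        seq = cds[name]
        if len(seq) % 3:
            raise ValueError(f"CDS length of {name} is not a codon multiple")
        n_res = sum(1 for aa in prot if aa != GAP)
        if n_res * 3 > len(seq):
            raise ValueError(f"protein alignment of {name} longer than CDS")
        codons = []
        i = 0
        for aa in prot:
            if aa == GAP:
                codons.append(GAP * 3)
            else:
                codons.append(seq[3 * i:3 * i + 3])
                i += 1
        out[name] = "".join(codons)
    return out


def trim_alignment(codon_alignment: dict[str, str],
                   min_occupancy: float = 0.5) -> dict[str, str]:
    """Drop codon columns whose non-gap occupancy is below the threshold."""
    seqs = list(codon_alignment.values())
    if not seqs or len({len(s) for s in seqs}) != 1 or len(seqs[0]) % 3:
        raise ValueError("need equal-length codon-multiple alignments")
    n_col = len(seqs[0]) // 3
    keep = []
    for c in range(n_col):
        occ = sum(1 for s in seqs if GAP not in s[3 * c:3 * c + 3])
        if occ / len(seqs) >= min_occupancy:
            keep.append(c)
    return {name: "".join(s[3 * c:3 * c + 3] for c in keep)
            for name, s in codon_alignment.items()}


def passes_length_gate(alignment: dict[str, str],
                       min_len_bp: int = MIN_ALIGNMENT_BP) -> bool:
    return bool(alignment) and len(next(iter(alignment.values()))) >= min_len_bp


def p_distance(a: str, b: str) -> float:
    """Proportion of differing, mutually ungapped sites."""
    pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not pairs:
        return 0.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def nj_tree(sequences: dict[str, str]) -> str:
    """Neighbor-joining newick from pairwise p-distances."""
    names = sorted(sequences)
    header = "," + ",".join(names)
    lines = [header]
    for a in names:
        row = [a] + [f"{p_distance(sequences[a], sequences[b]):.8f}"
                     for b in names]
        lines.append(",".join(row))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=io.StringIO("\n".join(lines)), delimiter=",")
    tree = pdm.nj_tree()
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
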