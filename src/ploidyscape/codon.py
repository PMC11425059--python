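"""Standard genetic code tables and per-site synonymous fractions.

These tables back both the codon simulator and the NG86 counting estimator.
Convention: a change that creates a stop codon counts as nonsynonymous when
tallying site fractions (the denominator at each codon position is always 3).
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for stop codons
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(codon: str) -> str:
    return GENETIC_CODE[codon]


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 single-base changes at `pos` that are synonymous."""
    aa = GENETIC_CODE[codon]
    n_syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if GENETIC_CODE[alt] == aa and alt not in STOP_CODONS:
            n_syn += 1
    return n_syn / 3.0


#: codon -> (f0, f1, f2): synonymous fraction at each position (stops excluded)
SYN_FRACTION: dict[str, tuple[float, float, float]] = {
    c: (_syn_fraction(c, 0), _syn_fraction(c, 1), _syn_fraction(c, 2))
    for c in SENSE_CODONS
}


def syn_sites(codon: str) -> float:
    """NG86 synonymous sites contributed by one codon (0..3)."""
    return sum(SYN_FRACTION[codon])


def classify_change(codon: str, pos: int, new_base: str) -> str:
    """Classify a single-base change: 'syn', 'nonsyn', or 'stop'."""
    alt = codon[:pos] + new_base + codon[pos + 1 :]
    if alt in STOP_CODONS:
        return "stop"
    return "syn" if GENETIC_CODE[alt] == GENETIC_CODE[codon] else "nonsyn"


def _nonsyn_nonstop_bases(codon: str, pos: int) -> tuple[str, ...]:
    out = []
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt not in STOP_CODONS and GENETIC_CODE[alt] != GENETIC_CODE[codon]:
            out.append(b)
    return tuple(out)


#: (codon, pos) -> bases giving a nonsynonymous, non-stop change
NONSYN_NONSTOP: dict[tuple[str, int], tuple[str, ...]] = {
    (c, p): _nonsyn_nonstop_bases(c, p)
    for c in SENSE_CODONS for p in range(3)
}
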