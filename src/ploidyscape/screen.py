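"""Screening gene families to 2:2:2:1 ohnolog quartets with synteny support.

The target pattern is two retained WGD copies in each of the three
Acipenseriform genomes (S, R, P) plus a single-copy outgroup gene (L).
Collinearity blocks are consumed from MCScan-style anchor tables, never
computed here; a quartet is collinearity-supported when each within-species
duplicate pair occurs as an anchor pair in some within-species block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

SPECIES_TAGS = ("S", "R", "P", "L")
QUARTET_PATTERN = {"S": 2, "R": 2, "P": 2, "L": 1}


class UnplacedGeneError(KeyError):
    pass


@dataclass
class GeneFamily:
    family_id: str
    members: dict[str, str]          # gene_id -> species tag

    def copy_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in SPECIES_TAGS}
        for sp in self.members.values():
            if sp not in counts:
                raise ValueError(f"unknown species tag {sp!r} "
                                 f"in family {self.family_id}")
            counts[sp] += 1
        return counts


@dataclass
class OhnologQuartet:
    family_id: str
    copies: dict[str, str]           # copy label (S1..L1) -> gene_id
    collinearity_supported: bool | None = None
    support_reason: str | None = None
    chromosomes: dict[str, str] = field(default_factory=dict)


@dataclass
class ScreenResult:
    accepted: list[OhnologQuartet]
    rejected: list[tuple[str, str]]  # (family_id, reason code)


def read_family_table(path) -> list[GeneFamily]:
    """OrthoFinder-style long table: family_id, species, gene_id (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fams = []
    for fid, grp in df.groupby("family_id", sort=True):
        fams.append(GeneFamily(
            family_id=str(fid),
            members=dict(zip(grp["gene_id"], grp["species"]))))
    return fams


def read_anchor_table(path) -> pd.DataFrame:
    """Minimal MCScan-style anchors: geneA, geneB, block_id, score (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"geneA": str, "geneB": str,
                                            "block_id": str})
    missing = {"geneA", "geneB", "block_id"} - set(df.columns)
    if missing:
        raise ValueError(f"anchor table missing columns: {sorted(missing)}")
    return df


def read_placement_table(path) -> pd.DataFrame:
    """Gene placements: gene_id, chromosome, start, end, strand (1-based)."""
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str,
                                              "chromosome": str})


def filter_copy_pattern(families: list[GeneFamily],
                        pattern: dict[str, int] | None = None) -> ScreenResult:
    """Keep exactly the families matching the 2:2:2:1 copy pattern.

    Rejections carry a reason code: missing_species(X), too_few(X), or
    too_many(X) for the first offending species in S, R, P, L order.
    """
    pattern = dict(QUARTET_PATTERN if pattern is None else pattern)
    accepted: list[OhnologQuartet] = []
    rejected: list[tuple[str, str]] = []
    for fam in families:
        counts = fam.copy_counts()
        reason = None
        for sp in SPECIES_TAGS:
            want = pattern.get(sp, 0)
            have = counts.get(sp, 0)
            if have == want:
                continue
            if have == 0:
                reason = f"missing_species({sp})"
            elif have < want:
                reason = f"too_few({sp})"
            else:
                reason = f"too_many({sp})"
            break
        if reason is not None:
            rejected.append((fam.family_id, reason))
            continue
        copies: dict[str, str] = {}
        for sp in SPECIES_TAGS:
            genes = sorted(g for g, s in fam.members.items() if s == sp)
            for i, g in enumerate(genes, start=1):
                copies[f"{sp}{i}"] = g
        accepted.append(OhnologQuartet(family_id=fam.family_id, copies=copies))
    return ScreenResult(accepted=accepted, rejected=rejected)


def build_anchor_pairs(anchors: pd.DataFrame) -> set[frozenset]:
    return {frozenset((a, b))
            for a, b in zip(anchors["geneA"], anchors["geneB"])}


def collinearity_support(quartet: OhnologQuartet,
                         anchor_pairs: set[frozenset],
                         placed_genes: set[str] | None = None,
                         ) -> tuple[bool, str | None]:
    """True iff each within-species duplicate pair is an anchor pair.

    ``placed_genes``, when given, is the set of genes with a chromosome
    placement; an unplaced quartet member raises UnplacedGeneError.
    """
    if placed_genes is not None:
        for label, gene in quartet.copies.items():
            if gene not in placed_genes:
                raise UnplacedGeneError(
                    f"gene {gene} ({label}) absent from placement table")
    for sp in ("S", "R", "P"):
        pair = frozenset((quartet.copies[f"{sp}1"], quartet.copies[f"{sp}2"]))
        if pair not in anchor_pairs:
            quartet.collinearity_supported = False
            quartet.support_reason = sp
            return False, sp
    quartet.collinearity_supported = True
    quartet.support_reason = None
    return True, None


def attach_chromosomes(quartets: list[OhnologQuartet],
                       placement: pd.DataFrame) -> None:
    chrom = dict(zip(placement["gene_id"], placement["chromosome"]))
    for q in quartets:
        q.chromosomes = {label: chrom.get(gene, "NA")
                         for label, gene in q.copies.items()}
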