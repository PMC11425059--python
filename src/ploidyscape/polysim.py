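"""Synthetic polyploid genomes, reads, variant counts, and k-mer pairs.

Everything here plants a known truth table so the inference modules can be
scored against it: heterozygous sites carry a genotype class (AB .. AAAABBBB)
giving the copy-number split of the two alleles among the homologs, reads are
sampled per homolog at Poisson depth, and k-mer pairs can also be drawn
directly from their Poisson coverage model for large-n studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP = str.maketrans("ACGT", "TGCA")


def _canonical_str(kmer: str) -> str:
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


def parse_genotype_class(name: str) -> tuple[int, int]:
    """'AAAB' -> (3, 1): copies of major allele A and minor allele B."""
    a = name.count("A")
    b = name.count("B")
    if a + b != len(name) or a < b or b < 1:
        raise ValueError(f"malformed genotype class {name!r}")
    return a, b


def genotype_class_name(a: int, b: int) -> str:
    return "A" * a + "B" * b


@dataclass(frozen=True)
class PolyploidGenomeConfig:
    ploidy_max: int = 8
    genotype_mixture: dict[str, float] = field(
        default_factory=lambda: {"AB": 1.0})
    haploid_coverage: float = 30.0
    error_rate: float = 0.0
    genome_len: int = 200_000
    read_len: int = 100
    k: int = 21
    het_spacing: int = 60          # min distance between planted sites
    het_density: float = 0.004     # sites per base (upper bound)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy_max not in (2, 4, 6, 8):
            raise ValueError("ploidy_max must be one of 2, 4, 6, 8")
        tot = sum(self.genotype_mixture.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError("genotype mixture proportions must sum to 1")
        for cls in self.genotype_mixture:
            a, b = parse_genotype_class(cls)
            if a + b > self.ploidy_max:
                raise ValueError(f"class {cls} exceeds ploidy_max")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must lie in [0, 0.05)")
        if self.genome_len < self.read_len:
            raise ValueError("genome_len must be >= read_len")


def _random_genome(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASE_ARR[rng.integers(0, 4, size=n)]


def simulate_polyploid_reads(
        config: PolyploidGenomeConfig,
        return_read_info: bool = False,
) -> tuple[list[str], pd.DataFrame] | tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Reads plus a truth table of planted heterozygous variant sites.

    At each planted site the two alleles A and B occupy a+b of the homologs
    (the site's genotype class).  When a+b is smaller than the ploidy, the
    remaining homologs are locally diverged (a third allele at the site plus
    flanking substitutions within half a k-mer) so that their k-mers neither
    pair with nor inflate the A/B alleles — the smudge of such a site really
    is its genotype class.

    Returns (reads, truth) and, when requested, a read_info table
    (start, homolog) aligned with the reads list.  Truth columns: site_id,
    pos (0-based), genotype_class, ref_base, alt_base, n_minor_copies,
    n_copies.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 11)))
    ref = _random_genome(cfg.genome_len, rng)

    # plant het sites on a grid so neighbouring sites never share a k-mer
    spacing = max(cfg.het_spacing, 3 * cfg.k)
    grid = np.arange(spacing, cfg.genome_len - spacing, spacing)
    n_sites = min(len(grid), int(cfg.het_density * cfg.genome_len))
    positions = np.sort(rng.choice(grid, size=n_sites, replace=False))

    classes = list(cfg.genotype_mixture)
    probs = np.array([cfg.genotype_mixture[c] for c in classes])
    site_classes = rng.choice(len(classes), size=n_sites, p=probs)

    n_hom = cfg.ploidy_max
    offset = cfg.k // 2
    homologs = [ref.copy() for _ in range(n_hom)]
    rows = []
    for sid, (pos, ci) in enumerate(zip(positions, site_classes)):
        cls = classes[ci]
        a, b = parse_genotype_class(cls)
        n_total = a + b
        perm = rng.permutation(n_hom)
        minor_carriers = perm[:b]
        outsiders = perm[n_total:]
        ref_base = ref[pos]
        base_idx = int(np.where(_BASE_ARR == ref_base)[0][0])
        alt = _BASE_ARR[(base_idx + 1 + int(rng.integers(0, 3))) % 4]
        alt_idx = int(np.where(_BASE_ARR == alt)[0][0])
        third = _BASE_ARR[next(i for i in range(4)
                               if i not in (base_idx, alt_idx))]
        for h in minor_carriers:
            homologs[h][pos] = alt
        for h in outsiders:
            # break every k-window that covers pos with >= 2 mismatches
            homologs[h][pos] = third
            for p in (pos - offset, pos + offset):
                homologs[h][p] = _BASE_ARR[
                    (int(np.where(_BASE_ARR == ref[p])[0][0]) + 2) % 4]
        # centred allele k-mers, canonical: lets callers validate recovery
        w0 = pos - cfg.k // 2
        win = ref[w0:w0 + cfg.k].tobytes().decode("ascii")
        mid = cfg.k // 2
        kmer_a = _canonical_str(win[:mid] + chr(ref_base) + win[mid + 1:])
        kmer_b = _canonical_str(win[:mid] + chr(alt) + win[mid + 1:])
        rows.append((f"site{sid:05d}", int(pos), cls,
                     chr(ref_base), chr(alt), b, n_total, kmer_a, kmer_b))
    truth = pd.DataFrame(rows, columns=[
        "site_id", "pos", "genotype_class", "ref_base", "alt_base",
        "n_minor_copies", "n_copies", "kmer_a", "kmer_b"])

    reads: list[str] = []
    info_rows: list[tuple[int, int]] = []
    n_reads_per_hom = rng.poisson(
        cfg.haploid_coverage * cfg.genome_len / cfg.read_len, size=n_hom)
    for h, n_reads in enumerate(n_reads_per_hom):
        starts = rng.integers(0, cfg.genome_len - cfg.read_len + 1,
                              size=n_reads)
        for s in starts:
            seq = homologs[h][s:s + cfg.read_len].copy()
            if cfg.error_rate > 0:
                err = rng.random(cfg.read_len) < cfg.error_rate
                if err.any():
                    shift = rng.integers(1, 4, size=int(err.sum()))
                    idx = np.searchsorted(_BASE_ARR, seq[err])
                    seq[err] = _BASE_ARR[(idx + shift) % 4]
            reads.append(seq.tobytes().decode("ascii"))
            info_rows.append((int(s), h))
    if return_read_info:
        info = pd.DataFrame(info_rows, columns=["start", "homolog"])
        return reads, truth, info
    return reads, truth


def variant_counts_from_reads(reads: list[str], read_info: pd.DataFrame,
                              truth: pd.DataFrame,
                              read_len: int) -> pd.DataFrame:
    """Per-site A/B allele read counts recovered from simulated reads.

    Only reads carrying the site's planted ref or alt allele are counted
    (diverged homologs carry a third state); output matches the
    simulate_variant_counts schema with the minor allele canonicalized.
    """
    starts = read_info["start"].to_numpy()
    order = np.argsort(starts, kind="stable")
    sorted_starts = starts[order]
    rows = []
    for rec in truth.itertuples():
        lo = np.searchsorted(sorted_starts, rec.pos - read_len + 1, "left")
        hi = np.searchsorted(sorted_starts, rec.pos, "right")
        n_ref = n_alt = 0
        for j in order[lo:hi]:
            base = reads[j][rec.pos - starts[j]]
            if base == rec.ref_base:
                n_ref += 1
            elif base == rec.alt_base:
                n_alt += 1
        depth = n_ref + n_alt
        if depth == 0:
            continue
        minor = min(n_ref, n_alt)
        rows.append((rec.site_id, depth, minor, rec.genotype_class))
    return pd.DataFrame(rows, columns=["site_id", "depth", "minor_count",
                                       "true_class"])


def simulate_variant_counts(ploidy: int, class_mixture: dict[str, float],
                            depth: float, n_sites: int,
                            seed: int = 0) -> pd.DataFrame:
    """Variant read-count table for planted genotype classes.

    A site of class with a+b = n copies has total depth ~ Poisson(n*depth)
    and minor-allele count ~ Binomial(depth_i, b/n): classes spanning fewer
    homologs than the ploidy (rediploidized regions) sit at proportionally
    lower depth, which is what gives the 4n vs 8n depth peaks of a
    frequency/depth profile.  ``depth`` is per-homolog coverage.
    """
    if ploidy % 2 or not 2 <= ploidy <= 8:
        raise ValueError("ploidy must be even, 2-8")
    if not class_mixture:
        raise ValueError("empty genotype mixture")
    tot = sum(class_mixture.values())
    if not math.isclose(tot, 1.0, abs_tol=1e-9):
        raise ValueError("mixture proportions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 22)))
    classes = list(class_mixture)
    probs = np.array([class_mixture[c] for c in classes])
    ab = np.array([parse_genotype_class(c) for c in classes], dtype=float)
    ns = ab.sum(axis=1)
    if (ns > ploidy).any():
        raise ValueError("genotype class exceeds the stated ploidy")
    fracs = ab[:, 1] / ns
    ci = rng.choice(len(classes), size=n_sites, p=probs)
    depths = rng.poisson(ns[ci] * depth)
    depths = np.maximum(depths, 1)
    minor = rng.binomial(depths, fracs[ci])
    # canonicalize to the minor allele
    flip = minor > depths - minor
    minor = np.where(flip, depths - minor, minor)
    return pd.DataFrame({
        "site_id": [f"v{i:06d}" for i in range(n_sites)],
        "depth": depths,
        "minor_count": minor,
        "true_class": [classes[i] for i in ci],
    })


def simulate_kmer_pairs(mixture: dict[str, float], haploid_coverage: float,
                        n_pairs: int, seed: int = 0) -> pd.DataFrame:
    """Heterozygous k-mer pair coverages drawn directly from the smudge model.

    For a pair of genotype class with a major / b minor copies, CovA ~
    Poisson(a*c) and CovB ~ Poisson(b*c) (zero-truncated); coverages are
    swapped where sampling inverts the order.  Columns: cov_major, cov_minor,
    true_class.
    """
    tot = sum(mixture.values())
    if not math.isclose(tot, 1.0, abs_tol=1e-9):
        raise ValueError("mixture proportions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 33)))
    classes = list(mixture)
    probs = np.array([mixture[c] for c in classes])
    ab = np.array([parse_genotype_class(c) for c in classes])
    ci = rng.choice(len(classes), size=n_pairs, p=probs)
    lam_a = ab[ci, 0] * haploid_coverage
    lam_b = ab[ci, 1] * haploid_coverage
    cov_a = rng.poisson(lam_a)
    cov_b = rng.poisson(lam_b)
    for cov, lam in ((cov_a, lam_a), (cov_b, lam_b)):
        zero = cov == 0
        while zero.any():  # zero-truncation: unobserved k-mers resampled
            cov[zero] = rng.poisson(lam[zero])
            zero = cov == 0
    major = np.maximum(cov_a, cov_b)
    minor = np.minimum(cov_a, cov_b)
    return pd.DataFrame({
        "cov_major": major,
        "cov_minor": minor,
        "true_class": [classes[i] for i in ci],
    })


def simulate_ssr_genotypes(n_loci: int, ploidy: int, allele_pool: int,
                           seed: int = 0) -> dict[str, list[int]]:
    """Microsatellite genotypes: per locus, `ploidy` allele draws from a
    uniform pool of `allele_pool` length variants."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 44)))
    out = {}
    for i in range(n_loci):
        alleles = rng.integers(0, allele_pool, size=ploidy)
        out[f"ssr{i:04d}"] = sorted(int(a) for a in alleles)
    return out
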