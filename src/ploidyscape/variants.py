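"""SNP allele-frequency/depth ploidy profiling, heterozygosity, SSR bounds.

A polyploid's heterozygous SNP sites cluster at minor-allele frequencies
b/n (b minor copies of n homologs): a tetraploid shows peaks at 1/4 and 1/2,
an octoploid adds 1/8 and 3/8.  The 2-D (frequency, depth) histogram makes
the ploidy classes visible as modes; the modal depths scale with n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import binom

from .polysim import genotype_class_name

#: canonical frequency grid for polyploid SNP peaks
FREQUENCY_GRID = (1 / 2, 1 / 4, 1 / 8, 3 / 8)


@dataclass
class FrequencyProfile:
    histogram: np.ndarray          # (freq_bins, depth_bins)
    freq_edges: np.ndarray
    depth_edges: np.ndarray
    peaks: list[tuple[float, float]]       # (frequency, depth) modes
    grid_matches: list[float | None]       # nearest grid frequency per peak

    @property
    def n_sites(self) -> int:
        return int(self.histogram.sum())


def _canonicalize(sites: pd.DataFrame) -> pd.DataFrame:
    df = sites.copy()
    if (df["depth"] < 1).any():
        raise ValueError("site depth must be >= 1")
    minor = np.minimum(df["minor_count"], df["depth"] - df["minor_count"])
    df["minor_count"] = minor
    df = df[df["minor_count"] > 0]
    return df


def build_frequency_profile(sites: pd.DataFrame, freq_bins: int = 50,
                            depth_bins: int = 24, bandwidth: float = 1.0,
                            peak_mass_fraction: float = 0.005,
                            grid_tolerance: float = 0.03,
                            ) -> FrequencyProfile:
    """2-D (minor-allele frequency, depth) histogram with detected modes.

    Peaks are strict local maxima of the Gaussian-smoothed histogram whose
    smoothed mass exceeds ``peak_mass_fraction`` of the sites; each peak
    frequency is matched to the canonical grid {1/2, 1/4, 1/8, 3/8} within
    ``grid_tolerance`` (None when no grid point is close).
    """
    if len(sites) < 1:
        raise ValueError("need at least one variant site")
    df = _canonicalize(sites)
    freq = (df["minor_count"] / df["depth"]).to_numpy()
    depth = df["depth"].to_numpy()
    hist, fe, de = np.histogram2d(
        freq, depth, bins=[freq_bins, depth_bins],
        range=[[0.0, 0.5], [0.0, float(depth.max()) + 1]])
    smooth = ndimage.gaussian_filter(hist, sigma=bandwidth, mode="nearest")
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (smooth == ndimage.maximum_filter(
        smooth, footprint=footprint, mode="nearest"))
    threshold = peak_mass_fraction * hist.sum()
    candidates = np.argwhere(local_max & (smooth >= threshold))
    # keep one peak per plateau: drop candidates adjacent to a kept one
    peaks: list[tuple[float, float]] = []
    kept_idx: list[tuple[int, int]] = []
    for i, j in sorted(map(tuple, candidates),
                       key=lambda ij: -smooth[ij[0], ij[1]]):
        if any(abs(i - ki) <= 1 and abs(j - kj) <= 1 for ki, kj in kept_idx):
            continue
        kept_idx.append((i, j))
        peaks.append((float((fe[i] + fe[i + 1]) / 2),
                      float((de[j] + de[j + 1]) / 2)))
    peaks.sort()
    matches: list[float | None] = []
    for f, _ in peaks:
        near = min(FREQUENCY_GRID, key=lambda g: abs(g - f))
        matches.append(near if abs(near - f) <= grid_tolerance else None)
    return FrequencyProfile(hist, fe, de, peaks, matches)


def compute_heterozygosity(n_het_snps: int, genome_length: int,
                           ndigits: int | None = 2) -> float:
    """Heterozygous SNPs per 100 bp of genome, in percent."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if n_het_snps < 0:
        raise ValueError("n_het_snps must be non-negative")
    pct = 100.0 * n_het_snps / genome_length
    return round(pct, ndigits) if ndigits is not None else pct


def ssr_ploidy_bound(loci: dict[str, list] | pd.DataFrame) -> int:
    """Lower bound on ploidy: the largest distinct allele count at a locus."""
    if isinstance(loci, pd.DataFrame):
        groups = loci.groupby("locus_id")["allele"].nunique()
        if groups.empty:
            raise ValueError("need at least one SSR locus")
        return int(groups.max())
    if not loci:
        raise ValueError("need at least one SSR locus")
    return max(len(set(alleles)) for alleles in loci.values())


def profile_class_weights(sites: pd.DataFrame, ploidy: int) -> dict[str, float]:
    """Genotype-class mixture weights by per-site binomial ML assignment.

    Each site (depth d, minor m) is assigned the copy split b in 1..ploidy/2
    maximising Binomial(m; d, b/ploidy); weights are assignment fractions.
    """
    if ploidy % 2 or ploidy < 2:
        raise ValueError("ploidy must be even and >= 2")
    df = _canonicalize(sites)
    if df.empty:
        raise ValueError("no heterozygous sites after canonicalization")
    d = df["depth"].to_numpy()
    m = df["minor_count"].to_numpy()
    bs = np.arange(1, ploidy // 2 + 1)
    ll = np.stack([binom.logpmf(m, d, b / ploidy) for b in bs], axis=1)
    best = bs[np.argmax(ll, axis=1)]
    out = {}
    for b in bs:
        out[genotype_class_name(ploidy - b, b)] = float((best == b).mean())
    return out
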