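"""Heterozygous k-mer pair ("smudge") ploidy inference and k-mer histograms.

A heterozygous locus in a polyploid leaves two k-mer variants that differ at
exactly one base.  The pair's coverage sum CovA+CovB estimates n*c (n = total
copies at the locus, c = per-homolog read depth) and the minor fraction
CovB/(CovA+CovB) estimates b/n (b = minor-allele copies), so pairs cluster in
(log coverage-sum, minor-fraction) space at centres indexed by genotype
classes AB, AAB, AAAB, AABB, ... up to the configured ploidy.  Assigning each
pair to its nearest centre yields the genome's ploidy composition, from which
an auto-/allo-polyploidy verdict is drawn.

K-mer counting is canonical (lexicographic minimum of a k-mer and its
reverse complement) and in-memory; 2-bit encoded, vectorized with numpy.
Counting is intended for desk-scale simulated data — external count tables
can be imported as TSV for anything larger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: ratio coordinate weight making adjacent minor-fraction separations at n=8
#: commensurate with log-coverage separations (configurable in the callers)
RATIO_WEIGHT = 4.0

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def reverse_complement(kmer: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(kmer))


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerHistogram:
    """Multiplicity spectrum: multiplicity -> number of distinct k-mers."""

    k: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not 3 <= self.k <= 31:
            # even k admits its own reverse complement; canonical form breaks
            raise ValueError("k must be odd and within [3, 31]")
        if any(m < 1 or c < 0 for m, c in self.counts.items()):
            raise ValueError("histogram entries must be non-negative")

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.counts.items())


@dataclass(frozen=True)
class KmerPairRecord:
    kmer_major: str | None
    kmer_minor: str | None
    cov_major: int
    cov_minor: int

    def __post_init__(self) -> None:
        if not self.cov_major >= self.cov_minor >= 1:
            raise ValueError("require cov_major >= cov_minor >= 1")


@dataclass
class PloidyComposition:
    proportions: dict[str, float]
    haploid_coverage_estimate: float
    n_pairs_used: int
    n_excluded: int = 0
    assignments: pd.DataFrame | None = None


@dataclass
class PolyploidyVerdict:
    mode: str                        # "auto" | "allo" | "ambiguous"
    auto_score: float
    rediploidization_index: float | None


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# counting


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical 2-bit integer codes of all N-free k-mers in one sequence."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes >= 0
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        ok &= valid[j:j + n - k + 1]
    fwd = np.zeros(n - k + 1, dtype=np.int64)
    rev = np.zeros(n - k + 1, dtype=np.int64)
    comp = 3 - codes
    for j in range(k):
        fwd = (fwd << 2) | np.where(valid[j:j + n - k + 1],
                                    codes[j:j + n - k + 1], 0)
        rev |= np.where(valid[j:j + n - k + 1],
                        comp[j:j + n - k + 1], 0) << (2 * j)
    return np.minimum(fwd, rev)[ok]


def _decode(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


def count_kmers(sequences: list[str] | str,
                k: int) -> tuple[KmerHistogram, dict[str, int]]:
    """Canonical k-mer counts over sequences; k-mers containing N skipped."""
    if isinstance(sequences, str):
        sequences = [sequences]
    if not sequences:
        raise ValueError("no sequences supplied")
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical form is ambiguous "
                         "for even k)")
    # one vectorized pass over everything; the N separators mask the joins
    allk = _encode_kmers("N".join(sequences), k)
    uniq, cnt = np.unique(allk, return_counts=True)
    table = {_decode(int(u), k): int(c) for u, c in zip(uniq, cnt)}
    mult, nkm = np.unique(cnt, return_counts=True)
    hist = KmerHistogram(k=k, counts={int(m): int(c)
                                      for m, c in zip(mult, nkm)})
    return hist, table


# ---------------------------------------------------------------------------
# heterozygous pair detection


def find_het_pairs(kmer_table: dict[str, int],
                   low_cov_threshold: int = 14) -> list[KmerPairRecord]:
    """One-mismatch heterozygous k-mer pairs above a coverage threshold.

    Both members must reach `low_cov_threshold` (the error trough of the
    k-mer spectrum).  When a k-mer has several candidate partners, only
    mutual best partners (most similar coverage; ties broken
    lexicographically) are kept, which drops unresolved multi-way families.
    """
    if low_cov_threshold < 1:
        raise ValueError("threshold must be >= 1")
    passed = {km: c for km, c in kmer_table.items() if c >= low_cov_threshold}
    best: dict[str, str] = {}
    for km, cov in passed.items():
        cand: list[tuple[int, str]] = []
        for pos in range(len(km)):
            for b in "ACGT":
                if b == km[pos]:
                    continue
                alt = canonical(km[:pos] + b + km[pos + 1:])
                if alt != km and alt in passed:
                    cand.append((abs(passed[alt] - cov), alt))
        if cand:
            best[km] = min(cand)[1]
    pairs: list[KmerPairRecord] = []
    for km, partner in best.items():
        if km < partner and best.get(partner) == km:
            ca, cb = passed[km], passed[partner]
            if ca >= cb:
                major, minor = km, partner
            else:
                major, minor = partner, km
                ca, cb = cb, ca
            pairs.append(KmerPairRecord(major, minor, ca, cb))
    return pairs


def pairs_to_frame(pairs: list[KmerPairRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "cov_major": [p.cov_major for p in pairs],
        "cov_minor": [p.cov_minor for p in pairs],
    })


def _as_cov_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        a = pairs["cov_major"].to_numpy(dtype=float)
        b = pairs["cov_minor"].to_numpy(dtype=float)
    else:
        a = np.array([p.cov_major for p in pairs], dtype=float)
        b = np.array([p.cov_minor for p in pairs], dtype=float)
    if np.any(b < 1) or np.any(a < b):
        raise ValueError("coverages must satisfy cov_major >= cov_minor >= 1")
    return a, b


# ---------------------------------------------------------------------------
# smudge geometry


def genotype_classes(ploidy_max: int) -> list[tuple[str, int, int]]:
    """(name, a, b) for all classes with 2 <= a+b <= ploidy_max, b <= a.

    Ordered by (total copies, minor copies): the tie-break order for
    equidistant centres (parsimony first, then A-skew).
    """
    out = []
    for n in range(2, ploidy_max + 1):
        for b in range(1, n // 2 + 1):
            out.append(("A" * (n - b) + "B" * b, n - b, b))
    return out


def _center_coords(classes, c: float) -> tuple[np.ndarray, np.ndarray]:
    ns = np.array([a + b for _, a, b in classes], dtype=float)
    bs = np.array([b for _, a, b in classes], dtype=float)
    return np.log(ns * c), bs / ns


def _log_component_matrix(cov_major: np.ndarray, cov_minor: np.ndarray,
                          c: float, classes) -> np.ndarray:
    """Log density of each observed (major, minor) pair under each class.

    The coverage model is CovA ~ Poisson(a*c), CovB ~ Poisson(b*c) observed
    as the sorted pair (major >= minor); both orderings contribute.
    """
    from scipy.special import logsumexp
    from scipy.stats import poisson

    a_ = np.array([a for _, a, _ in classes], dtype=float) * c
    b_ = np.array([b for _, _, b in classes], dtype=float) * c
    x = cov_major[:, None]
    y = cov_minor[:, None]
    ll1 = poisson.logpmf(x, a_[None, :]) + poisson.logpmf(y, b_[None, :])
    ll2 = poisson.logpmf(x, b_[None, :]) + poisson.logpmf(y, a_[None, :])
    M = np.logaddexp(ll1, ll2)
    tie = (cov_major == cov_minor)[:, None]
    return np.where(tie, M - np.log(2.0), M)


def _fit_mixture_weights(M: np.ndarray, max_iter: int = 500,
                         rtol: float = 1e-10) -> tuple[np.ndarray, float]:
    """EM over mixture weights with fixed components.

    Returns (weights, mean per-pair log-likelihood); deterministic.
    """
    from scipy.special import logsumexp

    n, k = M.shape
    logw = np.full(k, -np.log(k))
    prev = -np.inf
    for _ in range(max_iter):
        R = M + logw[None, :]
        Z = logsumexp(R, axis=1)
        ll = float(Z.mean())
        resp = np.exp(R - Z[:, None])
        w = np.clip(resp.mean(axis=0), 1e-12, None)
        w /= w.sum()
        logw = np.log(w)
        if abs(ll - prev) < rtol * max(1.0, abs(ll)):
            break
        prev = ll
    return np.exp(logw), ll


def _euclidean_cost(cov_major: np.ndarray, cov_minor: np.ndarray, c: float,
                    classes, ratio_weight: float = RATIO_WEIGHT) -> np.ndarray:
    """Squared distance in (log coverage-sum, weighted minor-fraction) space
    to the class centre (log(n*c), b/n) — the classical smudge geometry,
    kept as an alternative to the Poisson likelihood."""
    s = cov_major + cov_minor
    ratio = cov_minor / s
    cx, cy = _center_coords(classes, c)
    dx = np.log(s)[:, None] - cx[None, :]
    dy = (ratio[:, None] - cy[None, :]) * ratio_weight
    return dx * dx + dy * dy


def estimate_haploid_coverage(pairs, ploidy_max: int = 8,
                              parsimony_tolerance: float = 0.01) -> float:
    """Per-homolog (1n) coverage anchor from the pair cloud.

    The modal coverage-sum row of the cloud sits at n*c for some integer
    n <= ploidy_max.  Each candidate c = mode/n is scored by the maximum
    mixture log-likelihood over genotype-class weights (EM with components
    fixed at (a*c, b*c)).  Halving c can only add components and thus never
    fits worse, so the LARGEST candidate within ``parsimony_tolerance``
    (per-pair log-likelihood units) of the best wins — the parsimonious,
    fewest-copies reading.  The winner is then refined by alternating MAP
    assignment with the closed-form coverage update sum(Cov)/sum(copies).
    """
    from scipy.stats import gaussian_kde

    a, b = _as_cov_arrays(pairs)
    if a.size < 100:
        raise InsufficientDataError(
            f"need >= 100 pairs to anchor coverage, got {a.size}")
    s = a + b
    classes = genotype_classes(ploidy_max)
    copies = np.array([na + nb for _, na, nb in classes], dtype=float)

    # modal coverage-sum row of the pair cloud (kernel density on log sums)
    logs = np.log(s)
    grid = np.linspace(logs.min(), logs.max(), 512)
    dens = gaussian_kde(logs)(grid) if np.ptp(logs) > 0 else None
    s_star = float(np.exp(grid[np.argmax(dens)])) if dens is not None \
        else float(s[0])

    def refine(c: float, n_iter: int = 3) -> tuple[float, float]:
        """Alternate MAP assignment with the closed-form coverage update
        sum(Cov)/sum(copies); return (refined c, mixture log-likelihood)."""
        ll = -np.inf
        for _ in range(n_iter):
            M = _log_component_matrix(a, b, c, classes)
            w, ll = _fit_mixture_weights(M)
            idx = np.argmax(np.round(M + np.log(w)[None, :], 10), axis=1)
            c = float(s.sum() / copies[idx].sum())
        return c, ll

    # each candidate is refined before comparison: the kernel mode can miss
    # the true row centre by a few percent, which dense low-c class grids
    # would otherwise absorb better than the correct sparse grid
    cand = [refine(s_star / n) for n in range(2, ploidy_max + 1)]
    lls = np.array([ll for _, ll in cand])
    ok = np.flatnonzero(lls >= lls.max() - parsimony_tolerance)
    return cand[int(ok.min())][0]   # candidates are descending in c


def assign_smudges(pairs, haploid_coverage: float, ploidy_max: int = 8,
                   proportions_from: str = "mixture",
                   repeat_factor: float = 1.5) -> PloidyComposition:
    """Genotype-class composition of the heterozygous pair cloud.

    Mixture weights over the classes are estimated by EM with components
    fixed at (a*c, b*c); each pair is then assigned to its maximum-
    posterior class (equal posteriors resolve to the smaller total copy
    number, then the more A-skewed class).  Reported proportions are the
    mixture weights by default ('mixture'), which stay consistent when
    neighbouring smudges overlap; 'assigned' reports the fractions of
    hard-assigned pairs instead.  Pairs with coverage sum above
    repeat_factor * (ploidy_max + 1) * c are repeat-like and excluded
    (counted in n_excluded).
    """
    if haploid_coverage <= 0:
        raise ValueError("haploid_coverage must be positive")
    if ploidy_max not in (2, 4, 6, 8):
        raise ValueError("ploidy_max must be one of 2, 4, 6, 8")
    if proportions_from not in ("mixture", "assigned"):
        raise ValueError("proportions_from must be 'mixture' or 'assigned'")
    a, b = _as_cov_arrays(pairs)
    s = a + b
    keep = s <= repeat_factor * (ploidy_max + 1) * haploid_coverage
    n_excluded = int((~keep).sum())
    classes = genotype_classes(ploidy_max)
    names = [nm for nm, _, _ in classes]
    proportions = {nm: 0.0 for nm in names}
    assignments = None
    n_used = int(keep.sum())
    if n_used:
        M = _log_component_matrix(a[keep], b[keep], haploid_coverage,
                                  classes)
        w, _ = _fit_mixture_weights(M)
        # argmax returns the first maximum; class order implements the
        # (smaller n, then smaller b) tie-break
        idx = np.argmax(np.round(M + np.log(w)[None, :], 10), axis=1)
        labels = np.array(names, dtype=object)[idx]
        if proportions_from == "mixture":
            for nm, wk in zip(names, w):
                proportions[nm] = float(wk)
        else:
            uniq, cnt = np.unique(labels, return_counts=True)
            for nm, c_ in zip(uniq, cnt):
                proportions[str(nm)] = c_ / n_used
        assignments = pd.DataFrame({
            "cov_major": a[keep].astype(int),
            "cov_minor": b[keep].astype(int),
            "genotype_class": labels,
        })
    return PloidyComposition(
        proportions=proportions,
        haploid_coverage_estimate=float(haploid_coverage),
        n_pairs_used=n_used,
        n_excluded=n_excluded,
        assignments=assignments,
    )


# ---------------------------------------------------------------------------
# auto/allo verdict


def classify_polyploidy_mode(composition: PloidyComposition,
                             dominance_threshold: float = 0.40,
                             min_polyploid_mass: float = 0.10,
                             ) -> PolyploidyVerdict:
    """Auto- vs allo-polyploidy from the genotype-class composition.

    allo: AB is the strict plurality class and exceeds the dominance
    threshold (diverged subgenomes pair their k-mers one-to-one).  auto: the
    A-skewed classes (AAAB, AAAAAB, AAAAAABB, ...) together with balanced
    classes of four or more copies dominate instead.  Anything else —
    including an essentially diploid composition — is ambiguous.
    """
    p = composition.proportions
    total = sum(p.values())
    if total and not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError("proportions must sum to 1")
    ab = p.get("AB", 0.0)
    skewed = sum(v for k_, v in p.items()
                 if len(k_) >= 3 and k_.count("B") < len(k_) / 2)
    balanced_high = sum(v for k_, v in p.items()
                        if len(k_) >= 4 and k_.count("B") == len(k_) / 2)
    auto_score = skewed
    index_den = p.get("AABB", 0.0) + p.get("AAAB", 0.0)
    redip = p.get("AABB", 0.0) / index_den if index_den > 0 else None

    if 1.0 - ab < min_polyploid_mass:
        return PolyploidyVerdict("ambiguous", auto_score, redip)
    is_allo = (ab >= dominance_threshold
               and all(ab > v for k_, v in p.items() if k_ != "AB"))
    is_auto = (skewed + balanced_high >= dominance_threshold
               and skewed + balanced_high > ab)
    if is_allo == is_auto:
        mode = "ambiguous"
    else:
        mode = "allo" if is_allo else "auto"
    return PolyploidyVerdict(mode, auto_score, redip)


# ---------------------------------------------------------------------------
# genome size


def estimate_genome_size(histogram: KmerHistogram) -> float:
    """total k-mers / modal depth, excluding the low-multiplicity error tail.

    The peak is the modal multiplicity above the first trough (local
    minimum) of the spectrum; a monotone spectrum has no interior peak and
    is rejected.
    """
    if not histogram.counts:
        raise InsufficientDataError("empty histogram")
    max_m = max(histogram.counts)
    arr = np.zeros(max_m + 2, dtype=float)
    for m, c in histogram.counts.items():
        arr[m] = c
    trough = None
    for m in range(1, max_m):
        if arr[m] <= arr[m + 1]:
            trough = m
            break
    if trough is None:
        raise InsufficientDataError(
            "monotone k-mer spectrum: no interior coverage peak")
    peak_depth = trough + 1 + int(np.argmax(arr[trough + 1:max_m + 1]))
    return histogram.total_kmers / peak_depth
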