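"""Ka/Ks estimation (NG86), Ks mixture peaks, and Ks-proportional dating.

The counting estimator follows Nei & Gojobori: synonymous and nonsynonymous
sites are fractions of the three possible changes at each codon position
(averaged over the two sequences), observed differences are averaged over
all minimal substitution paths between differing codons, and proportions are
corrected for multiple hits with the Jukes-Cantor transform
d = -(3/4) ln(1 - 4p/3).  Ks peaks are located by Gaussian mixtures on
log-Ks with the component count chosen by BIC.  Events are dated
proportionally against a calibrated (age, Ks) anchor, absolute rates come
from Ks/(2T), and pseudogene escape ages follow a two-phase model in which a
copy evolves at a functional Ka/Ks ratio until it escapes constraint and
neutrally (ratio 1) afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .codon import GENETIC_CODE, STOP_CODONS, syn_sites

YEARS_PER_MY = 1.0e6


class SaturationError(ValueError):
    pass


class NoDataError(ValueError):
    pass


@dataclass
class KaKsEstimate:
    ka: float | None
    ks: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int
    saturated: bool = False
    has_internal_stop: bool = False

    @property
    def omega(self) -> float | None:
        if self.ka is None or self.ks in (None, 0.0):
            return None
        return self.ka / self.ks


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _codon_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over minimal substitution paths.

    Paths passing through stop codons are excluded unless every path does.
    Steps onto a stop codon, when such paths must be used, count as
    nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
                nd += 1
            elif GENETIC_CODE[cur] == GENETIC_CODE[nxt] \
                    and cur not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    clean = [(sd, nd) for ts, sd, nd in paths if not ts]
    use = clean if clean else [(sd, nd) for _, sd, nd in paths]
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _iter_codon_pairs(seq1: str, seq2: str):
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    for i in range(0, len(seq1) - len(seq1) % 3, 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        yield c1.upper(), c2.upper()


def ng86_kaks(seq1: str, seq2: str) -> KaKsEstimate:
    """NG86 Ka/Ks with Jukes-Cantor correction for one aligned pair.

    Codons containing gaps or ambiguity codes in either sequence are
    skipped; internal stop codons are skipped and flagged.  Symmetric in
    argument order.
    """
    S = N = Sd = Nd = 0.0
    n_codons = 0
    has_stop = False
    for c1, c2 in _iter_codon_pairs(seq1, seq2):
        if any(b not in "ACGT" for b in c1 + c2):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            has_stop = True
            continue
        s_here = (syn_sites(c1) + syn_sites(c2)) / 2.0
        S += s_here
        N += 3.0 - s_here
        sd, nd = _codon_path_diffs(c1, c2)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise NoDataError("no comparable codons in the aligned pair")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    return KaKsEstimate(
        ka=ka, ks=ks, syn_sites=S, nonsyn_sites=N, syn_diffs=Sd,
        nonsyn_diffs=Nd, n_codons=n_codons,
        saturated=(ks is None or ka is None), has_internal_stop=has_stop)


# ---------------------------------------------------------------------------
# family-level node-averaged Ks


WITHIN_SPECIES_PAIRS = (("S1", "S2"), ("R1", "R2"), ("P1", "P2"))


@dataclass
class FamilyKs:
    family_id: str
    dup_node_ks: float | None       # node-averaged Ks of the duplication node
    s_pair_ks: float | None         # within-S duplicate pair
    pair_ks: dict[str, float | None]
    n_saturated: int
    averaging: str = "arithmetic_mean_over_within_species_pairs"


def family_ks(sequences: dict[str, str], family_id: str = "") -> FamilyKs:
    """Node-averaged Ks values for one quartet family.

    The duplication-node Ks is the arithmetic mean of the within-species
    duplicate pair values (S1-S2, R1-R2, P1-P2); saturated pairs are
    excluded and counted.
    """
    pair_ks: dict[str, float | None] = {}
    n_sat = 0
    vals = []
    for a, b in WITHIN_SPECIES_PAIRS:
        if a not in sequences or b not in sequences:
            continue
        est = ng86_kaks(sequences[a], sequences[b])
        key = f"{a}-{b}"
        if est.saturated:
            pair_ks[key] = None
            n_sat += 1
        else:
            pair_ks[key] = est.ks
            vals.append(est.ks)
    dup = float(np.mean(vals)) if vals else None
    s_val = pair_ks.get("S1-S2")
    return FamilyKs(family_id=family_id, dup_node_ks=dup, s_pair_ks=s_val,
                    pair_ks=pair_ks, n_saturated=n_sat)


# ---------------------------------------------------------------------------
# Ks mixture fitting


@dataclass
class KsDistribution:
    values: np.ndarray
    n_components: int
    weights: np.ndarray
    means_log: np.ndarray
    variances_log: np.ndarray
    bic_trace: dict[int, float]
    log_scale: bool = True

    @property
    def component_modes(self) -> np.ndarray:
        """Component centres on the Ks scale (exp of log-means)."""
        return np.exp(self.means_log) if self.log_scale else self.means_log


def fit_ks_mixture(values, max_components: int = 4, log_scale: bool = True,
                   seed: int = 0) -> KsDistribution:
    """Gaussian mixture on (log-)Ks with BIC component selection.

    Deterministic given the seed: k-means initialization with 10 restarts.
    """
    from sklearn.mixture import GaussianMixture

    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size < 20:
        raise NoDataError(f"need >= 20 Ks values, got {vals.size}")
    if log_scale:
        if (vals <= 0).any():
            raise ValueError("log-scale fitting requires positive Ks values")
        x = np.log(vals)
    else:
        x = vals
    if np.allclose(x, x[0]):
        return KsDistribution(
            values=vals, n_components=1, weights=np.array([1.0]),
            means_log=np.array([x[0]]), variances_log=np.array([0.0]),
            bic_trace={}, log_scale=log_scale)
    X = x.reshape(-1, 1)
    bic: dict[int, float] = {}
    fits = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=10, init_params="kmeans",
                             random_state=seed)
        gm.fit(X)
        bic[k] = float(gm.bic(X))
        fits[k] = gm
    best = min(bic, key=lambda k: (bic[k], k))
    gm = fits[best]
    order = np.argsort(gm.means_.ravel())
    return KsDistribution(
        values=vals, n_components=best,
        weights=gm.weights_[order],
        means_log=gm.means_.ravel()[order],
        variances_log=gm.covariances_.ravel()[order],
        bic_trace=bic, log_scale=log_scale)


# ---------------------------------------------------------------------------
# dating


@dataclass(frozen=True)
class CalibratedEvent:
    name: str
    T_mya: float
    ks: float

    def __post_init__(self) -> None:
        if self.T_mya <= 0:
            raise ValueError("event age must be positive")
        if self.ks < 0:
            raise ValueError("event Ks must be non-negative")


def proportional_date(ks_event: float, reference: CalibratedEvent) -> float:
    """Age (MYA) of an event by linear Ks scaling against a reference."""
    if reference.ks <= 0:
        raise ValueError("reference event must have positive Ks")
    if ks_event < 0:
        raise ValueError("event Ks must be non-negative")
    return (ks_event / reference.ks) * reference.T_mya


def substitution_rate(ks: float, T_years: float) -> float:
    """Absolute synonymous rate per site per year: Ks / (2T)."""
    if T_years <= 0:
        raise ValueError("divergence time must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * T_years)


@dataclass
class EscapeEstimate:
    t_escape: float
    clipped: bool
    exceeds_neutral: bool = False


def pseudogene_escape_time(ka: float, ks: float, omega_func: float,
                           T_total: float,
                           neutral_tolerance: float = 0.25) -> EscapeEstimate:
    """Escape age under the two-phase constraint model.

    A copy evolving at ratio omega_func while functional and neutrally
    (ratio 1) after escaping at age T_e, over a total divergence span
    T_total, accumulates ka/ks = omega_func + (T_e/T_total)(1 - omega_func);
    inverting gives T_e = T_total (ka/ks - omega_func) / (1 - omega_func).
    Estimates outside [0, T_total] are clipped and flagged; ratios beyond
    1 + neutral_tolerance are additionally flagged as inconsistent with the
    model.
    """
    if not 0 < omega_func < 1:
        raise ValueError("omega_func must lie in (0, 1)")
    if ks <= 0:
        raise ValueError("ks must be positive")
    if T_total <= 0:
        raise ValueError("T_total must be positive")
    ratio = ka / ks
    if ratio < omega_func - 1e-12:
        # below the functional ratio: treat as never escaped
        return EscapeEstimate(t_escape=0.0, clipped=True)
    exceeds = ratio > 1.0 + neutral_tolerance
    t_e = T_total * (ratio - omega_func) / (1.0 - omega_func)
    clipped = t_e < 0 or t_e > T_total
    t_e = min(max(t_e, 0.0), T_total)
    return EscapeEstimate(t_escape=t_e, clipped=clipped,
                          exceeds_neutral=exceeds)


# ---------------------------------------------------------------------------
# supermatrix export


@dataclass
class Supermatrix:
    sequences: dict[str, str]                  # taxon -> concatenated CDS
    partitions: list[tuple[str, int, int]]     # (family_id, start, end) 1-based

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def export_supermatrix(families: list[tuple[str, dict[str, str]]],
                       ) -> Supermatrix:
    """Concatenate per-family alignments in the given order.

    ``families`` is a list of (family_id, taxon -> aligned CDS); all members
    of one family must share a length.  Missing taxa are not allowed — the
    matrix is built from complete quartets only.
    """
    if not families:
        raise NoDataError("no families to concatenate")
    taxa = sorted(families[0][1])
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for fid, seqs in families:
        if sorted(seqs) != taxa:
            raise ValueError(f"family {fid}: taxon set mismatch")
        lens = {len(s) for s in seqs.values()}
        if len(lens) != 1:
            raise ValueError(f"family {fid}: members differ in length")
        (L,) = lens
        for t in taxa:
            chunks[t].append(seqs[t])
        partitions.append((fid, pos + 1, pos + L))
        pos += L
    return Supermatrix(
        sequences={t: "".join(chunks[t]) for t in taxa},
        partitions=partitions)


def write_supermatrix_phylip(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f" {len(sm.sequences)} {sm.length}\n")
        for taxon in sorted(sm.sequences):
            fh.write(f"{taxon}  {sm.sequences[taxon]}\n")


def write_supermatrix_fasta(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(sm.sequences):
            fh.write(f">{taxon}\n{sm.sequences[taxon]}\n")


def write_partition_table(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tstart\tend\n")
        for fid, start, end in sm.partitions:
            fh.write(f"{fid}\t{start}\t{end}\n")


def read_supermatrix_phylip(path) -> Supermatrix:
    with open(path) as fh:
        header = fh.readline().split()
        n, L = int(header[0]), int(header[1])
        seqs = {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            seqs[name] = seq.strip()
    if len(seqs) != n or any(len(s) != L for s in seqs.values()):
        raise ValueError("malformed PHYLIP supermatrix")
    return Supermatrix(sequences=seqs, partitions=[])
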