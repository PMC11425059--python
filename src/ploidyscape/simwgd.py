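"""Synthetic gene-family histories under shared WGD with delayed rediploidization.

The simulator realises a four-taxon history: an outgroup L; then an ingroup
that underwent a shared whole-genome duplication (WGD) and later speciated
into P and, after a second split, S and R.  Each locus carries one
rediploidization age drawn from a configurable law; duplicated copies are
treated as freely exchanging (indistinguishable) until that age and diverge
afterwards.  A locus whose rediploidization predates the P split yields the
AORe topology PSR-PSR; later rediploidization yields the LORe topologies
PP-SR-SR or PP-SS-RR depending on which speciations it postdates.

Codon evolution is a per-site candidate-substitution process: candidate
events arrive at rate ``syn_rate`` per nucleotide site per year, synonymous
changes are always accepted, and nonsynonymous changes (stop-creating ones
redirected onto sense alternatives) are accepted with probability omega.
Under this process the expected synonymous divergence between two copies separated
for time t is 2*syn_rate*t per synonymous site, and the realised Ka/Ks
equals omega — so counting estimators downstream are unbiased in
expectation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .codon import BASES, NONSYN_NONSTOP, SENSE_CODONS, classify_change

YEARS_PER_MY = 1.0e6

COPY_LABELS = ("P1", "P2", "S1", "S2", "R1", "R2", "L1")

#: rediploidization law: ("point", age) | ("uniform", lo, hi) |
#: ("prompt_or_delayed", p_delayed) | callable(rng) -> age in MYA
RediploidizationLaw = tuple | Callable[[np.random.Generator], float]


class HistoryError(ValueError):
    """Raised for configurations describing an inconsistent event history."""


@dataclass(frozen=True)
class HistoryConfig:
    """Event ages (MYA), molecular rates, and sampling sizes for one run."""

    t_wgd_shared: float = 210.7
    t_split_P: float = 150.0
    t_split_SR: float = 87.4
    t_wgd_S: float = 35.12
    t_split_outgroup: float = 345.0
    rediploidization_law: RediploidizationLaw = ("uniform", 0.0, None)
    syn_rate: float = 3.13e-10  # synonymous substitutions / site / year
    omega_func: float = 0.2
    omega_neutral: float = 1.0
    n_families: int = 200
    seq_len_codons: int = 150
    n_chromosomes: int = 33
    n_macro: int = 6
    pseudogene_prob: float = 0.0
    block_mode: bool = False  # one rediploidization age per chromosome
    seed: int = 0

    def __post_init__(self) -> None:
        ages = (self.t_wgd_shared, self.t_split_P, self.t_split_SR,
                self.t_wgd_S, self.t_split_outgroup)
        if any(not math.isfinite(a) or a < 0 for a in ages):
            raise HistoryError("all event ages must be finite and non-negative")
        if not (self.t_wgd_shared > self.t_split_P > self.t_split_SR >= 0):
            raise HistoryError(
                "require t_wgd_shared > t_split_P > t_split_SR >= 0, got "
                f"{self.t_wgd_shared} / {self.t_split_P} / {self.t_split_SR}")
        if self.t_split_outgroup <= self.t_wgd_shared:
            raise HistoryError("outgroup split must predate the shared WGD")
        if not 0 < self.omega_func < 1:
            raise HistoryError("omega_func must lie in (0, 1)")
        if self.syn_rate <= 0:
            raise HistoryError("syn_rate must be positive")
        if self.n_families < 1 or self.seq_len_codons < 1:
            raise HistoryError("n_families and seq_len_codons must be >= 1")
        if not 0 <= self.pseudogene_prob <= 1:
            raise HistoryError("pseudogene_prob must lie in [0, 1]")


@dataclass
class SimulatedFamily:
    family_id: str
    true_class: str                      # "AORe" | "LORe"
    topology: str                        # "PSR_PSR" | "PP_SR_SR" | "PP_SS_RR"
    redip_age_mya: float
    true_tree: str                       # newick, branch lengths in years
    sequences: dict[str, str] | None     # copy label -> CDS
    chromosome: int
    chrom_class: str                     # "macro" | "medium_micro"
    pseudogene_escape: dict[str, float] = field(default_factory=dict)

    @property
    def chromosome_assignment(self) -> dict[str, str]:
        return {c: self.chrom_class for c in COPY_LABELS}


# ---------------------------------------------------------------------------
# rediploidization laws


def draw_rediploidization_age(law: RediploidizationLaw, cfg: HistoryConfig,
                              rng: np.random.Generator) -> float:
    if callable(law):
        age = float(law(rng))
    else:
        kind = law[0]
        if kind == "point":
            age = float(law[1])
        elif kind == "uniform":
            lo = float(law[1])
            hi = cfg.t_wgd_shared if law[2] is None else float(law[2])
            age = float(rng.uniform(lo, hi))
        elif kind == "prompt_or_delayed":
            p_delayed = float(law[1])
            if rng.random() < p_delayed:
                age = float(rng.uniform(0.0, cfg.t_split_P))
            else:
                age = cfg.t_wgd_shared
        else:
            raise HistoryError(f"unknown rediploidization law: {law!r}")
    if not 0.0 <= age <= cfg.t_wgd_shared:
        raise HistoryError(
            f"rediploidization age {age} outside [0, {cfg.t_wgd_shared}]")
    return age


def expected_topology(redip_age: float, cfg: HistoryConfig) -> str:
    """Topology implied by one locus's rediploidization age."""
    if redip_age >= cfg.t_split_P:
        return "PSR_PSR"
    if redip_age >= cfg.t_split_SR:
        return "PP_SR_SR"
    return "PP_SS_RR"


def resolution_class(topology: str) -> str:
    return "AORe" if topology == "PSR_PSR" else "LORe"


# ---------------------------------------------------------------------------
# gene-tree construction


@dataclass
class _Node:
    age: float                       # years before present
    label: str | None = None
    children: list["_Node"] = field(default_factory=list)

    def newick(self) -> str:
        return self._nwk(parent_age=None) + ";"

    def _nwk(self, parent_age: float | None) -> str:
        if self.children:
            inner = ",".join(c._nwk(self.age) for c in self.children)
            body = f"({inner})"
        else:
            body = self.label or ""
        if parent_age is None:
            return body
        return f"{body}:{parent_age - self.age:.6g}"


def _leaf(label: str) -> _Node:
    return _Node(age=0.0, label=label)


def _species_pair(label: str, t_dup: float) -> _Node:
    return _Node(age=t_dup, children=[_leaf(f"{label}1"), _leaf(f"{label}2")])


def build_true_tree(redip_age: float, cfg: HistoryConfig) -> _Node:
    """Rooted 7-leaf gene tree (ages in years) for one locus."""
    t_r = redip_age * YEARS_PER_MY
    t_p = cfg.t_split_P * YEARS_PER_MY
    t_sr = cfg.t_split_SR * YEARS_PER_MY
    t_out = cfg.t_split_outgroup * YEARS_PER_MY

    topo = expected_topology(redip_age, cfg)
    if topo == "PSR_PSR":
        def copy_subtree(i: int) -> _Node:
            sr = _Node(age=t_sr, children=[_leaf(f"S{i}"), _leaf(f"R{i}")])
            return _Node(age=t_p, children=[_leaf(f"P{i}"), sr])
        ingroup = _Node(age=t_r, children=[copy_subtree(1), copy_subtree(2)])
    elif topo == "PP_SR_SR":
        def sr_copy(i: int) -> _Node:
            return _Node(age=t_sr, children=[_leaf(f"S{i}"), _leaf(f"R{i}")])
        sr_dup = _Node(age=t_r, children=[sr_copy(1), sr_copy(2)])
        ingroup = _Node(age=t_p, children=[_species_pair("P", t_r), sr_dup])
    else:  # PP_SS_RR
        sr = _Node(age=t_sr, children=[_species_pair("S", t_r),
                                       _species_pair("R", t_r)])
        ingroup = _Node(age=t_p, children=[_species_pair("P", t_r), sr])
    return _Node(age=t_out, children=[_leaf("L1"), ingroup])


# ---------------------------------------------------------------------------
# codon evolution


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def evolve_branch(seq: str, duration_years: float, syn_rate: float,
                  omega: float, rng: np.random.Generator) -> str:
    """Evolve one branch with constant omega (candidate/rejection process)."""
    return evolve_branch_two_phase(seq, duration_years, syn_rate,
                                   [(duration_years, omega)], rng)


def evolve_branch_two_phase(seq: str, duration_years: float, syn_rate: float,
                            segments: Sequence[tuple[float, float]],
                            rng: np.random.Generator) -> str:
    """Evolve along segments of (duration_years, omega), in order.

    Total segment durations must equal ``duration_years``.  Changes that
    would create a stop codon count as nonsynonymous flux but are redirected
    onto a uniformly chosen non-stop nonsynonymous alternative at the same
    position, so sequences stay sense-only while the realised
    nonsynonymous flux per NG86 nonsynonymous site is exactly
    omega * syn_rate.
    """
    total = sum(d for d, _ in segments)
    if not math.isclose(total, duration_years, rel_tol=1e-9, abs_tol=1e-3):
        raise ValueError("segment durations must sum to the branch duration")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    n_sites = len(seq)
    for seg_t, omega in segments:
        n_events = rng.poisson(syn_rate * n_sites * seg_t)
        for _ in range(n_events):
            site = int(rng.integers(0, n_sites))
            ci, pos = divmod(site, 3)
            codon = codons[ci]
            old = codon[pos]
            # uniform draw over the 3 non-identical bases
            new = BASES[(BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
            kind = classify_change(codon, pos, new)
            if kind != "syn":
                if rng.random() >= omega:
                    continue
                if kind == "stop":
                    alts = NONSYN_NONSTOP[(codon, pos)]
                    if not alts:
                        continue
                    new = alts[int(rng.integers(0, len(alts)))]
            codons[ci] = codon[:pos] + new + codon[pos + 1 :]
    return "".join(codons)


def _evolve_tree(node: _Node, seq: str, cfg: HistoryConfig,
                 rng: np.random.Generator,
                 pseudo: dict[str, float]) -> dict[str, str]:
    """Recursively evolve sequences down the tree; returns leaf sequences."""
    out: dict[str, str] = {}
    for child in node.children:
        t = node.age - child.age
        if child.label is not None and child.label in pseudo:
            t_escape = pseudo[child.label] * YEARS_PER_MY
            t_escape = min(t_escape, t)
            segs = [(t - t_escape, cfg.omega_func),
                    (t_escape, cfg.omega_neutral)]
            child_seq = evolve_branch_two_phase(seq, t, cfg.syn_rate, segs, rng)
        else:
            child_seq = evolve_branch(seq, t, cfg.syn_rate, cfg.omega_func, rng)
        if child.label is not None:
            out[child.label] = child_seq
        else:
            out.update(_evolve_tree(child, child_seq, cfg, rng, pseudo))
    return out


# ---------------------------------------------------------------------------
# main entry points


def simulate_families(config: HistoryConfig,
                      with_sequences: bool = True) -> list[SimulatedFamily]:
    """Draw ``config.n_families`` loci; deterministic given ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    block_ages: dict[int, float] = {}
    families: list[SimulatedFamily] = []
    for i in range(config.n_families):
        chrom = int(rng.integers(1, config.n_chromosomes + 1))
        if config.block_mode:
            if chrom not in block_ages:
                block_ages[chrom] = draw_rediploidization_age(
                    config.rediploidization_law, config, rng)
            t_r = block_ages[chrom]
        else:
            t_r = draw_rediploidization_age(
                config.rediploidization_law, config, rng)
        topo = expected_topology(t_r, config)
        tree = build_true_tree(t_r, config)

        pseudo: dict[str, float] = {}
        if config.pseudogene_prob > 0 and rng.random() < config.pseudogene_prob:
            # the second S copy loses constraint at a uniform escape age
            pseudo["S2"] = float(rng.uniform(0.0, min(t_r, config.t_split_SR)
                                             if topo != "PSR_PSR" else t_r))

        seqs: dict[str, str] | None = None
        if with_sequences:
            root_seq = random_cds(config.seq_len_codons, rng)
            seqs = _evolve_tree(tree, root_seq, config, rng, pseudo)

        families.append(SimulatedFamily(
            family_id=f"fam{i:05d}",
            true_class=resolution_class(topo),
            topology=topo,
            redip_age_mya=t_r,
            true_tree=tree.newick(),
            sequences=seqs,
            chromosome=chrom,
            chrom_class="macro" if chrom <= config.n_macro else "medium_micro",
            pseudogene_escape=pseudo,
        ))
    return families


def simulate_pseudogene_loci(n_loci: int, t_total_my: float,
                             escape_age_my: float | Callable | None,
                             omega_func: float, syn_rate: float,
                             seq_len_codons: int = 300,
                             seed: int = 0) -> list[tuple[str, str, float]]:
    """Single-branch pseudogene loci: (ancestor, descendant, escape age).

    Each locus evolves for ``t_total_my`` under omega_func, switching to
    neutral evolution at the planted escape age (years before present).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 77)))
    t_total = t_total_my * YEARS_PER_MY
    out = []
    for _ in range(n_loci):
        if escape_age_my is None:
            t_e = float(rng.uniform(0.0, t_total_my))
        elif callable(escape_age_my):
            t_e = float(escape_age_my(rng))
        else:
            t_e = float(escape_age_my)
        anc = random_cds(seq_len_codons, rng)
        segs = [(t_total - t_e * YEARS_PER_MY, omega_func),
                (t_e * YEARS_PER_MY, 1.0)]
        desc = evolve_branch_two_phase(anc, t_total, syn_rate, segs, rng)
        out.append((anc, desc, t_e))
    return out


def aore_fraction_expected(cfg: HistoryConfig) -> float:
    """Closed-form AORe probability under the uniform law on [0, t_wgd]."""
    return (cfg.t_wgd_shared - cfg.t_split_P) / cfg.t_wgd_shared


def config_to_dict(cfg: HistoryConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if callable(d["rediploidization_law"]):
        d["rediploidization_law"] = "<callable>"
    else:
        d["rediploidization_law"] = list(d["rediploidization_law"])
    return d
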