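"""Stage orchestration: reproducible multi-stage runs with manifests.

Stages run in dependency order (simulate -> screen -> classify -> date, with
independent smudge and variants paths); all randomness flows from one run
seed through named per-stage substreams, so identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import dating, kmer, polysim, screen, simwgd, trees, variants
from .io import write_fasta

STAGES = ("simulate", "smudge", "variants", "screen", "classify", "date")

#: per-stage seed substream offsets (stable across runs)
_STAGE_STREAM = {name: i + 1 for i, name in enumerate(STAGES)}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    stages: list[str]
    out_dir: str
    seed: int = 1
    # simulate
    n_families: int = 60
    seq_len_codons: int = 120
    rediploidization_law: tuple = ("prompt_or_delayed", 0.387)
    history: dict = field(default_factory=dict)
    # smudge
    k: int = 21
    min_cov: int = 14
    ploidy_max: int = 8
    haploid_coverage: float = 25.0
    genotype_mixture: dict = field(default_factory=lambda: {
        "AB": 0.04, "AAAB": 0.32, "AABB": 0.20, "AAAABB": 0.03,
        "AAAAAAAB": 0.12, "AAAAAABB": 0.11, "AAAAABBB": 0.08,
        "AAAABBBB": 0.10})
    n_pairs: int = 8000
    # variants
    variant_depth: float = 12.0
    n_sites: int = 20000
    # classify
    support_threshold: float | None = None
    # date
    calibration: dict = field(default_factory=lambda: {
        "name": "shared_wgd", "T_mya": 210.7, "ks": 0.132})

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES) - {"all"}
        if unknown:
            raise ConfigError(f"unknown stage name(s): {sorted(unknown)}")
        if "all" in self.stages:
            self.stages = list(STAGES)
        if not self.stages:
            raise ConfigError("no stages selected")
        # dependency check: inputs must be produced by an earlier stage
        sel = [s for s in STAGES if s in self.stages]
        for s, deps in {"screen": ["simulate"], "classify": ["simulate"],
                        "date": ["simulate"]}.items():
            if s in sel and not all(d in sel for d in deps):
                raise ConfigError(
                    f"stage {s!r} requires stage(s) {deps} in this run "
                    "(external inputs are driven via the library API)")
        self.stages = sel


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str
    stages_run: list[str]
    row_counts: dict[str, int]
    checksums: dict[str, str]
    warnings: list[str]
    failed_stage: str | None = None
    elapsed_s: float = 0.0

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence(
        (seed, _STAGE_STREAM[stage])).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig) -> RunManifest:
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    warnings: list[str] = []
    manifest = RunManifest(
        config=dataclasses.asdict(config), seed=config.seed,
        package_version=__version__, stages_run=[], row_counts=counts,
        checksums={}, warnings=warnings)
    families = None
    labels_df = None
    try:
        if "simulate" in config.stages:
            families = _stage_simulate(config, out, counts)
            manifest.stages_run.append("simulate")
        if "smudge" in config.stages:
            _stage_smudge(config, out, counts, warnings)
            manifest.stages_run.append("smudge")
        if "variants" in config.stages:
            _stage_variants(config, out, counts)
            manifest.stages_run.append("variants")
        if "screen" in config.stages:
            _stage_screen(config, out, counts, families)
            manifest.stages_run.append("screen")
        if "classify" in config.stages:
            labels_df = _stage_classify(config, out, counts, families)
            manifest.stages_run.append("classify")
        if "date" in config.stages:
            _stage_date(config, out, counts, families, labels_df)
            manifest.stages_run.append("date")
    except Exception:
        done = set(manifest.stages_run)
        manifest.failed_stage = next(
            (s for s in config.stages if s not in done), None)
        manifest.elapsed_s = time.time() - t0
        manifest.write(out / "manifest.json")
        raise
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.checksums[f.name] = _sha256(f)
    manifest.elapsed_s = time.time() - t0
    manifest.write(out / "manifest.json")
    return manifest


def _history_config(config: RunConfig, seed: int) -> simwgd.HistoryConfig:
    kwargs = dict(config.history)
    kwargs.setdefault("rediploidization_law",
                      tuple(config.rediploidization_law))
    kwargs.setdefault("n_families", config.n_families)
    kwargs.setdefault("seq_len_codons", config.seq_len_codons)
    kwargs["seed"] = seed
    return simwgd.HistoryConfig(**kwargs)


def _stage_simulate(config, out: Path, counts) -> list[simwgd.SimulatedFamily]:
    cfg = _history_config(config, _stage_seed(config.seed, "simulate"))
    families = simwgd.simulate_families(cfg)
    fam_dir = out / "families"
    fam_dir.mkdir(exist_ok=True)
    rows = []
    for fam in families:
        write_fasta(fam.sequences, fam_dir / f"{fam.family_id}.fasta")
        (fam_dir / f"{fam.family_id}.nwk").write_text(fam.true_tree + "\n")
        rows.append((fam.family_id, fam.true_class, fam.topology,
                     fam.redip_age_mya, fam.chromosome, fam.chrom_class))
    truth = pd.DataFrame(rows, columns=[
        "family_id", "true_class", "topology", "redip_age_mya",
        "chromosome", "chrom_class"])
    truth.to_csv(out / "family_truth.tsv", sep="\t", index=False)
    (out / "history_config.json").write_text(
        json.dumps(simwgd.config_to_dict(cfg), indent=2, sort_keys=True)
        + "\n")
    counts["families"] = len(families)
    return families


def _stage_smudge(config, out: Path, counts, warnings) -> None:
    pairs = polysim.simulate_kmer_pairs(
        config.genotype_mixture, config.haploid_coverage, config.n_pairs,
        seed=_stage_seed(config.seed, "smudge"))
    cov = kmer.estimate_haploid_coverage(pairs, config.ploidy_max)
    comp = kmer.assign_smudges(pairs, cov, config.ploidy_max)
    verdict = kmer.classify_polyploidy_mode(comp)
    if comp.n_excluded:
        warnings.append(f"smudge: {comp.n_excluded} repeat-like pairs "
                        "excluded")
    pd.DataFrame(sorted(comp.proportions.items()),
                 columns=["genotype_class", "proportion"]).to_csv(
        out / "smudge_composition.tsv", sep="\t", index=False)
    (out / "smudge_verdict.json").write_text(json.dumps({
        "mode": verdict.mode, "auto_score": verdict.auto_score,
        "rediploidization_index": verdict.rediploidization_index,
        "haploid_coverage_estimate": comp.haploid_coverage_estimate,
        "n_pairs_used": comp.n_pairs_used,
        "n_excluded": comp.n_excluded}, indent=2, sort_keys=True) + "\n")
    counts["kmer_pairs"] = int(comp.n_pairs_used + comp.n_excluded)


def _stage_variants(config, out: Path, counts) -> None:
    sites = polysim.simulate_variant_counts(
        config.ploidy_max, config.genotype_mixture, config.variant_depth,
        config.n_sites, seed=_stage_seed(config.seed, "variants"))
    sites.to_csv(out / "variant_sites.tsv", sep="\t", index=False)
    profile = variants.build_frequency_profile(sites)
    (out / "variant_profile.json").write_text(json.dumps({
        "n_sites": profile.n_sites,
        "peaks": [[round(f, 4), round(d, 2)] for f, d in profile.peaks],
        "grid_matches": profile.grid_matches}, indent=2) + "\n")
    counts["variant_sites"] = len(sites)


def _families_to_gene_families(families) -> list[screen.GeneFamily]:
    out = []
    for fam in families:
        members = {f"{fam.family_id}_{c}": c[0] for c in fam.sequences}
        out.append(screen.GeneFamily(family_id=fam.family_id,
                                     members=members))
    return out


def _stage_screen(config, out: Path, counts, families) -> None:
    if families is None:
        raise ConfigError("screen stage requires simulated families")
    result = screen.filter_copy_pattern(_families_to_gene_families(families))
    pd.DataFrame(
        [(q.family_id, ",".join(q.copies.values())) for q in result.accepted],
        columns=["family_id", "copies"]).to_csv(
        out / "quartets.tsv", sep="\t", index=False)
    counts["quartets_accepted"] = len(result.accepted)
    counts["quartets_rejected"] = len(result.rejected)


def _stage_classify(config, out: Path, counts, families) -> pd.DataFrame:
    if families is None:
        raise ConfigError("classify stage requires simulated families")
    rows = []
    for fam in families:
        rooted = trees.root_with_outgroup(fam.true_tree)
        lab = trees.classify_topology(rooted, config.support_threshold)
        rows.append((fam.family_id, lab.label, lab.resolution_class,
                     str(fam.chromosome), fam.chrom_class))
    df = pd.DataFrame(rows, columns=["family_id", "label",
                                     "resolution_class", "chromosome",
                                     "size_class"])
    df.to_csv(out / "topology_labels.tsv", sep="\t", index=False)
    summary = trees.summarize_proportions(
        [trees.TopologyLabel.of(l) for l in df["label"]])
    chrom = trees.chrom_distribution(df)
    (out / "topology_summary.json").write_text(json.dumps({
        "counts": summary.counts,
        "proportions": {k: round(v, 4)
                        for k, v in summary.proportions.items()},
        "chrom_test": {
            "t_stat": chrom.t_stat, "p_value": chrom.p_value,
            "direction": chrom.direction,
            "test_defined": chrom.test_defined}},
        indent=2, sort_keys=True) + "\n")
    counts["classified_families"] = summary.n_classifiable
    return df


def _stage_date(config, out: Path, counts, families, labels_df) -> None:
    if families is None:
        raise ConfigError("date stage requires simulated families")
    label_map = {}
    if labels_df is not None:
        label_map = dict(zip(labels_df["family_id"],
                             labels_df["resolution_class"]))
    rows = []
    aore_values = []
    aore_alignments = []
    for fam in families:
        fk = dating.family_ks(fam.sequences, fam.family_id)
        cls = label_map.get(fam.family_id, fam.true_class)
        rows.append((fam.family_id, cls, fk.dup_node_ks, fk.s_pair_ks,
                     fk.n_saturated))
        if cls == "AORe" and fk.dup_node_ks is not None:
            aore_values.append(fk.dup_node_ks)
            aore_alignments.append((fam.family_id, fam.sequences))
    ks_df = pd.DataFrame(rows, columns=["family_id", "resolution_class",
                                        "dup_node_ks", "s_pair_ks",
                                        "n_saturated"])
    ks_df.to_csv(out / "family_ks.tsv", sep="\t", index=False)

    ref = dating.CalibratedEvent(config.calibration["name"],
                                 config.calibration["T_mya"],
                                 config.calibration["ks"])
    report: dict = {"reference": dataclasses.asdict(ref)}
    if len(aore_values) >= 20:
        mix = dating.fit_ks_mixture(
            aore_values, seed=_stage_seed(config.seed, "date"))
        main_ks = float(mix.component_modes[int(np.argmax(mix.weights))])
        report["mixture"] = {
            "n_components": mix.n_components,
            "modes_ks": [round(float(m), 5) for m in mix.component_modes],
            "weights": [round(float(w), 4) for w in mix.weights]}
    else:
        main_ks = float(np.median(aore_values)) if aore_values else float("nan")
    report["aore_peak_ks"] = round(main_ks, 5)
    report["aore_peak_age_mya"] = round(
        dating.proportional_date(main_ks, ref), 2)
    report["substitution_rate_per_year"] = dating.substitution_rate(
        main_ks, ref.T_mya * 1e6)
    (out / "dating_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")

    if aore_alignments:
        sm = dating.export_supermatrix(aore_alignments)
        dating.write_supermatrix_phylip(sm, out / "supermatrix.phy")
        dating.write_supermatrix_fasta(sm, out / "supermatrix.fasta")
        dating.write_partition_table(sm, out / "supermatrix_partitions.tsv")
    counts["ks_families"] = len(ks_df)
    counts["aore_supermatrix_families"] = len(aore_alignments)


def make_fixtures(seed: int, out_dir) -> RunManifest:
    """Write a miniature end-to-end dataset with truth tables.

    Families are drawn from a law mixing prompt and delayed rediploidization
    so every topology class appears; a toy polyploid read set and variant /
    SSR tables accompany them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = RunConfig(stages=["all"], out_dir=str(out), seed=seed,
                       n_families=50, seq_len_codons=100)
    manifest = run_pipeline(config)
    # toy polyploid read set (~200 kb genome)
    pcfg = polysim.PolyploidGenomeConfig(
        ploidy_max=4, genotype_mixture={"AAAB": 0.5, "AABB": 0.5},
        haploid_coverage=12.0, genome_len=200_000, seed=seed)
    reads, truth = polysim.simulate_polyploid_reads(pcfg)
    write_fasta({f"read{i:06d}": r for i, r in enumerate(reads)},
                out / "reads.fasta.gz")
    truth.to_csv(out / "read_truth.tsv", sep="\t", index=False)
    ssr = polysim.simulate_ssr_genotypes(60, 8, 12, seed=seed)
    with open(out / "ssr_genotypes.tsv", "w") as fh:
        fh.write("locus_id\tindividual\talleles\n")
        for locus, alleles in ssr.items():
            fh.write(f"{locus}\tind1\t{','.join(map(str, alleles))}\n")
    # assert coverage of every topology label by construction
    labels = {f.topology for f in simwgd.simulate_families(
        _history_config(config, _stage_seed(seed, "simulate")),
        with_sequences=False)}
    if labels != {"PSR_PSR", "PP_SR_SR", "PP_SS_RR"}:
        raise RuntimeError("fixture generator failed to cover all classes")
    return manifest
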