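"""Infer a genome's ploidy composition from heterozygous k-mer pairs.

Pairs are simulated from an octoploid-like genotype mixture; the smudge
analysis re-estimates the per-homolog coverage, the class proportions, and
an auto/allo-polyploidy verdict.
"""

from ploidyscape import kmer, polysim

truth = {"AB": 0.04, "AAAB": 0.32, "AABB": 0.20, "AAAABB": 0.03,
         "AAAAAAAB": 0.12, "AAAAAABB": 0.11, "AAAAABBB": 0.08,
         "AAAABBBB": 0.10}
pairs = polysim.simulate_kmer_pairs(truth, haploid_coverage=25.0,
                                    n_pairs=10_000, seed=2)

coverage = kmer.estimate_haploid_coverage(pairs, ploidy_max=8)
comp = kmer.assign_smudges(pairs, coverage, ploidy_max=8)
verdict = kmer.classify_polyploidy_mode(comp)

print(f"estimated 1n coverage: {coverage:.1f}x (planted 25.0x)")
print("recovered composition (planted in parentheses):")
for cls, w in sorted(comp.proportions.items(), key=lambda kv: -kv[1]):
    if w > 0.01:
        print(f"  {cls:>10}: {w:.3f}  ({truth.get(cls, 0.0):.2f})")
print(f"verdict: {verdict.mode} (auto score "
      f"{verdict.auto_score:.2f}, rediploidization index "
      f"{verdict.rediploidization_index:.2f})")
# A high share of A-skewed classes (AAAB, AAAAAAAB, ...) marks homologous
# (auto) WGD; an AB-dominated cloud would mark diverged subgenomes (allo).
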