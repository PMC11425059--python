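# Methods

## The event model

All histories follow one four-taxon scaffold: an outgroup lineage L splits
first (`t_split_outgroup`, default 345 MYA); the ingroup undergoes a shared
WGD (`t_wgd_shared`, default 210.7 MYA); lineage P splits off
(`t_split_P`, 150 MYA); S and R split last (`t_split_SR`, 87.4 MYA); S may
carry a second, lineage-specific WGD (`t_wgd_S`, 35.12 MYA).  Defaults are
the Acipenseriform ages the dating stage is calibrated against; the
S/R split default is the midpoint of the 85.3–89.5 MYA interval the
calibrated analysis brackets.  Configurations violating
`t_wgd_shared > t_split_P > t_split_SR ≥ 0` or with the outgroup younger
than the WGD are rejected.

Each locus draws one rediploidization age t_r from a configurable law.
Duplicated copies are treated as indistinguishable (freely exchanging)
until t_r and diverge afterwards, which fixes the gene-tree topology:

* t_r ≥ t_split_P → **PSR-PSR** (AORe): each post-WGD copy carries its own
  (P,(S,R)) species subtree.
* t_split_SR ≤ t_r < t_split_P → **PP-SR-SR** (LORe): P and the S/R
  ancestor resolve independently at t_r.
* t_r < t_split_SR → **PP-SS-RR** (LORe): all three terminal lineages
  resolve independently.

Rediploidization is per family; an optional *block mode* assigns one age
per simulated chromosome, giving the chromosome-level clustering the
enrichment test expects.  The first 6 of 33 simulated chromosomes are
"macro", families are placed uniformly.

### Rediploidization laws

The distribution of rediploidization ages in real genomes is unknown, so
the law is a configuration choice, never an assertion:

* `("point", age)` — degenerate (instant or never-resolved extremes);
* `("uniform", lo, hi)` — uninformative within `[0, t_wgd_shared]`;
* `("prompt_or_delayed", p)` — with probability 1−p the locus resolves at
  the WGD itself, otherwise uniformly after the first speciation.  This is
  the law used for dating studies here: it encodes the biological reading
  that AORe loci resolved early (their duplicate divergence marks the WGD)
  while LORe loci resolved after speciation.  Under a global uniform law
  even AORe duplicate pairs diverge well after the WGD, and no Ks-based
  estimator can recover the WGD age from them — an identifiability limit
  of the data, not of the implementation.  The default p = 0.387
  reproduces a ~61% AORe share.
* any callable `rng → age`.

## Codon evolution

Sequences are `seq_len_codons` sense codons (default 150).  Candidate
substitution events arrive at `syn_rate` per nucleotide site per year
(default 3.13e-10, the calibrated Acipenseriform synonymous rate); the
target base is uniform over the three alternatives.  Synonymous changes
are always accepted; nonsynonymous changes are accepted with probability
ω (`omega_func`, default 0.2).  A change that would create a stop codon
counts as nonsynonymous flux but is redirected onto a uniformly chosen
non-stop nonsynonymous alternative at the same position (rejected in the
rare case none exists), so sequences stay sense-only.

Two calibration identities follow, and the suite asserts both: the
synonymous divergence of two copies separated for time t is
2·`syn_rate`·t per NG86 synonymous site, and the realised Ka/Ks equals ω.
The redirection rule matters for the second identity: NG86 counts
stop-creating changes among the nonsynonymous site opportunities, so a
simulator that silently discards them depresses Ka by ~5%.

Pseudogenes follow a two-phase schedule: ω = `omega_func` until the drawn
escape age, ω = 1 afterwards.  `simulate_pseudogene_loci` evolves single
branches from a stored ancestor, which is the cleanest realisation of the
two-phase model (T_total is then the branch span); pair-based analyses
pass the pairwise span instead.

## Smudge analysis

K-mers are counted canonically (lexicographic minimum of k-mer and
reverse complement; odd k required, N-containing windows skipped) with a
2-bit vectorized counter meant for desk-scale data; larger tables import
as TSV.  Heterozygous pairs are k-mers at Hamming distance 1 in canonical
orientation, both above the error-trough threshold (default 14, the
published trough; `estimate_genome_size` finds the first local minimum of
a spectrum when asked).  Conflict resolution is mutual-best by coverage
similarity, ties lexicographic — k-mers in unresolved multi-way families
are dropped, and a brute-force all-vs-all oracle pins the behaviour on
toy genomes.

The coverage model is CovA ~ Poisson(a·c), CovB ~ Poisson(b·c).  The
haploid coverage anchor c is estimated by placing the modal coverage-sum
row at n·c and scoring each candidate c = mode/n by the maximised mixture
log-likelihood over class weights; because halving c only adds components
(its class set is a superset), the largest candidate within 0.01 per-pair
log-likelihood units of the best is accepted — the parsimonious,
fewest-copies reading.  A balanced single-class cloud (only AABB) is
genuinely indistinguishable from AB at twice the coverage; parsimony
resolves it to the lower ploidy by design.

Class proportions are EM-estimated mixture weights rather than
hard-assignment fractions: neighbouring smudges overlap at realistic
coverages (AABB vs AAABB at 20–25× confuse ~5–10% of pairs under any
hard rule), and the mixture weights are the consistent estimator of the
planted proportions.  Each pair still receives a maximum-posterior class
(ties resolve to fewer copies, then the more A-skewed class) for
per-pair tables, and `proportions_from="assigned"` restores the
hard-fraction behaviour.  Pairs with coverage sums beyond
1.5·(ploidy_max+1)·c are excluded as repeat-like and counted.  The
classical (log coverage-sum, weighted minor-fraction) Euclidean geometry
is retained as `_euclidean_cost` for comparison.

The auto/allo verdict: *allo* when AB is the strict plurality class at or
above the dominance threshold (default 0.40); *auto* when A-skewed classes
plus balanced classes of ≥4 copies reach the threshold and exceed AB;
ambiguous otherwise, including near-diploid compositions (polyploid mass
below 0.10) and the rare case both rules fire.  `auto_score` reports the
A-skewed sum; the rediploidization index is AABB/(AABB+AAAB).

## Variant and SSR profiling

Variant sites are canonicalized to the minor allele (frequency ≤ 0.5).
The 2-D frequency/depth histogram is smoothed with a Gaussian kernel
(σ = 1 bin); peaks are strict local maxima above a mass threshold
(default 0.5% of sites) and are matched to the grid {1/2, 1/4, 1/8, 3/8}
within ±0.03.  A genotype class with n = a+b copies is simulated at depth
Poisson(n·per-homolog depth) with minor count Binomial(depth, b/n), so
rediploidized (4n) classes sit at half the depth of 8n classes — the
depth stratification that separates the two in a profile.  Folding onto
the minor allele biases the mean of a Binomial(d, 1/2) class to
1/2 − 1/√(2πd); tests compare against that folded expectation.
Heterozygosity is 100·SNPs/genome length.  The SSR bound is the maximum
distinct allele count at any locus — a lower bound on ploidy.

## Screening and topology

Families are filtered to exactly S:R:P:L = 2:2:2:1 with exhaustive reason
codes.  Collinearity is consumed, not computed: a quartet is supported
when each within-species duplicate pair co-occurs as an anchor pair in an
MCScan-style 4-column table.  Alignment hygiene (codon back-translation,
≥50% column occupancy trimming, 150-bp length gate) and a neighbor-joining
fallback tree are provided for end-to-end runs; maximum-likelihood tree
inference is expected upstream.

Classification is clade-set membership on the rooted 6-leaf tree after
outgroup removal.  A single code path handles collapsed (multifurcating)
trees: a leaf set is realizable as a clade on some binary refinement iff
it is a union of children's leaf sets at one node; on binary trees this
reduces exactly to the clade set.  Binary trees assert mutual exclusivity
of the three definitions (proved exhaustively over all 945 rooted 6-leaf
trees); after support collapsing a tree is classified only when exactly
one definition is satisfiable — several give UNRESOLVED, none gives
OTHER.  Raising the support threshold therefore only moves named classes
toward UNRESOLVED.  Support values are read from internal node labels
(first "/"-token; values > 1 are treated as percentages).

The chromosome test is a two-sample Student's t on per-chromosome AORe
fractions, macro vs medium/micro; degenerate inputs (a size class with
fewer than 2 chromosomes) report the test as undefined, and zero-variance
groups short-circuit to t = 0, p = 1 (equal) or p = 0 (separated).

## Ka/Ks and dating

NG86 counting: per-codon synonymous site fractions over the three changes
at each position (stop-creating changes count as nonsynonymous
opportunities), averaged over the two sequences; observed differences
averaged over all minimal substitution paths, excluding paths through
stop codons unless every path is; separate Jukes–Cantor correction of the
two proportions, with p ≥ 3/4 flagged as saturation.  Codons with gaps,
ambiguity codes or stop codons are skipped (stops additionally flagged).
Sites always sum to 3 × compared codons, and the estimator is exactly
symmetric in its arguments.  NG86 was chosen over ML codon estimators
because it is fully specifiable and oracle-testable; at the Ks ≤ 0.2
divergences dated here the estimator family disagreement is small.

Family Ks: the duplication node is the arithmetic mean over within-species
duplicate pairs (S1-S2, R1-R2, P1-P2), saturated pairs excluded and
counted.  Mixtures are fitted on log-Ks with k-means initialisation and
10 fixed-seed restarts per component count, BIC-selected over
1..max_components; an all-equal input short-circuits to one zero-variance
component.  Dating is linear: T = (Ks/Ks_ref)·T_ref; rates are Ks/(2T).
The pseudogene escape formula T_e = T_total·(Ka/Ks − ω)/(1 − ω) is this
package's explicit reconstruction of the constraint-escape idea: the
cited literature states no equation, so the two-phase linear-accumulation
model is documented here as an interpretation, with estimates clipped to
[0, T_total] and flags for clipping and ratios beyond 1 + 0.25.

## What the simulations do and do not show

The generators reproduce the statistical structure the estimators assume:
Poisson coverage per homolog, independent uniform-target substitutions,
one rediploidization age per locus (or chromosome block), no indels, no
recombination within loci, uniform sequencing error, and genotype classes
planted at exactly their nominal copy numbers (diverged non-carrier
homologs are locally scrambled so they neither pair nor inflate allele
depths).  Passing tests therefore demonstrate correctness of the
inference under the stated model, and the size of purely statistical
biases (folded binomials, JC convexity, smudge overlap).  They do not
demonstrate robustness to repeat-rich genomes, mapping artefacts,
coverage waves, GC bias, selection heterogeneity or rate variation across
loci — with real data, the error-trough threshold, the repeat-exclusion
factor and the support threshold are the knobs that absorb part of this.

## Problem sizes

Suite and acceptance runs use desk-scale sizes chosen to keep statistical
power while remaining quick: 200 families × 150 codons for dating checks,
2000 families (trees only) for the AORe-fraction closed form, 20,000
k-mer pairs for mixture recovery, 200 pseudogene loci × 500 codons,
30–100 kb toy genomes for read-level paths, and exhaustive enumeration
(945 trees) where the space is finite.
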