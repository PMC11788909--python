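# Methods

This note records the models behind `capkin`, the parameters that matter,
the numerical choices made where the design was genuinely open, and what
the synthetic validation does and does not demonstrate about real capture
data.

## The synthetic half-sib generator

The generator emulates the data structure of a target-capture marker
study on open-pollinated families, the setting where small SNP panels are
used for pedigree confirmation and relatedness analysis.

**Pedigree.** Families are maternal half-sib: each family shares one
mother and every offspring has its own father. By default fathers are
never reused, so the expected additive relatedness between two family
members is exactly 0.25 (they share one parent) and between members of
different families exactly 0. An optional `provenance_founder_pool` draws
mothers and fathers from a finite per-provenance pool instead, inducing
background relatedness within provenances — real seed orchards show
elevated between-family relatedness within a provenance, but no published
value pins its magnitude, so the default keeps founders unrelated and the
pool size is left to the user. `families_per_provenance` accepts one count
per provenance, so unbalanced designs (e.g. 2+1+1 families of five across
three provenances, 20 individuals) are expressible directly.

**Genotypes.** Founder alternate-allele frequencies are drawn per locus
from Uniform(`maf_min`, `maf_max`), default [0.05, 0.5]. The lower bound
guarantees loci are informative and can survive a MAF ≥ 0.05 filter in the
noiseless limit; the upper bound makes the alternate allele the minor one.
Mother and father genotypes are Binomial(2, p) draws; each offspring
receives one Mendelian gamete from each parent (heterozygous parents
transmit a fair coin). Loci are unlinked — standard practice for kinship
panels, where markers are chosen to segregate independently — so there is
no linkage disequilibrium, shared ancestry tracts, or genome geography.

**Sequences.** Each locus is placed at a distinct random position in one
of `n_genes` random templates of `gene_length_bp`. An individual's gene
sequence carries its allele at each site; heterozygotes are written as the
IUPAC ambiguity code of {ref, alt}, giving one sequence per individual per
gene, pre-aligned by construction (no indels). This mirrors the
one-supercontig-per-individual inputs of real consensus building while
deliberately omitting alignment error, indels and paralogous copies.

**Observation layer.** Per-genotype read depth is negative-binomial with
mean `mean_depth` (default 30×) and dispersion `depth_dispersion`
(default 5, i.e. moderately overdispersed relative to Poisson, as capture
data is). With probability `genotype_error_rate` (default 0.01) a call is
flipped to a uniformly chosen different code; calls go missing
independently at `missing_rate` (default 0.05). GQ is a Phred-like map of
the error rate, round(−10·log₁₀ max(e, 10⁻⁹)) capped at 99 and jittered
±2 — a deliberately simple monotone map, sufficient to exercise a GQ
threshold; it does not model the depth- and allele-balance-dependence of
real caller GQs. Site MapQ is Normal(`mapq_mean` = 60, 2), rounded. The
noiseless limit reproduces the truth exactly, which anchors several tests.

All randomness descends from `SimConfig.seed` through named substreams
(pedigree / genotypes / sequences / observation / planting), so a config
is a complete, byte-reproducible specification of a dataset; no module
reads OS entropy.

## Consensus

`column_consensus` spreads each symbol's weight evenly over its IUPAC base
set (N counts ¼ toward each base), ignores gaps, and returns the top base
when its weight reaches `plurality_fraction` (default 0.5) of the non-gap
total. Exact ties return the IUPAC code of the tied set; a single top base
short of the plurality returns the code over all observed bases, so the
output's base set never exceeds what the column contains; all-gap columns
yield a gap, and gap-consensus columns are dropped by default to produce
an ungapped reference usable as a mapping and primer template. These are
EMBOSS-cons-like plurality semantics with one interpretable knob; the
tie-to-ambiguity rule is chosen for determinism and information
preservation rather than to mimic any particular tool's tie-breaking.

## Filter cascade

Rules run in a fixed order (indels, multiallelic, MAF, missingness, GQ,
MapQ, depth window, heterozygosity) and the report attributes each removed
locus to the first rule it failed; per-rule counts are only meaningful
with respect to this order. Defaults: MAF ≥ 0.05, missingness ≤ 0.1,
GQ > 16, MapQ > 40, mean depth within [0.5×, 2×] the global mean.
Choices worth stating:

- *Depth.* "Mean of the depth distribution" is read site-wise
  (VCFtools-like): per-locus mean depth over called genotypes, global mean
  of those means, window [0.5×, 2×]. The window is resolved from the
  input table before any rule runs and recorded in the report; it can be
  pinned explicitly (`min_dp`/`max_dp`) when thresholds should be carried
  across runs. The upper bound is the defence against collapsed paralogs,
  which inflate both depth and heterozygosity.
- *GQ.* By default a genotype-level mask: failing genotypes become
  missing and the missingness rule is re-applied, reproducing the
  practical effect of a genotype-quality filter followed by a
  missingness filter. A site-level switch (`gq_site_level`) drops any
  site with a failing genotype instead.
- *Small samples.* With cohorts of ~5 individuals frequency estimates are
  meaningless, so `small_sample_mode` keeps every polymorphic locus
  (monomorphic-only MAF rule) and tolerates no missing call. `maf_min=0`
  likewise means "drop monomorphic only".
- *Heterozygosity.* The optional cap removes loci with observed
  heterozygosity above 0.5, the theoretical maximum 2p(1−p) of a
  biallelic locus in Hardy–Weinberg proportions — excess heterozygosity
  being the signature of reads from collapsed duplicate regions. Named
  presets (`tightened_maf02`, `tightened_maf01`, `small_sample`) bundle
  the data-driven per-species tightenings as plain configs, not code
  branches.
- Multiallelic records are dropped whole, never decomposed.

The cascade is deterministic and monotone: raising `maf_min`, `gq_min`,
`mapq_min` or lowering `max_missing_fraction` can only shrink the
survivor set (the depth window is fixed from the input, which is what
makes this exact). Re-applying the cascade to its own output makes no
further removals for realistic depth distributions; a pathological depth
distribution could in principle shift the recomputed window enough to cut
a survivor on the second pass, which is why the window can be pinned.

## VanRaden relatedness

`vanraden_grm` implements the first VanRaden formulation with a single
global denominator: Z = M − 2p, G = ZZᵀ / (2 Σ pⱼ(1−pⱼ)). Missing codes
are mean-imputed to 2pⱼ before centering (filtered inputs carry at most
~10% missingness, so the impact is bounded); loci fixed under the supplied
frequencies are excluded from numerator and denominator alike and the
locus count actually used is recorded. The per-locus-scaled variant is out
of scope.

Allele frequencies may come from the sample or from an external panel.
The distinction matters: frequencies estimated from a small sample
containing relatives systematically *underestimate* relatedness, more so
for related pairs — with sample frequencies the centered matrix has
zero column sums, so every row of G averages to ~0 and within-family
means land visibly below 0.25 in small cohorts (the worked example in the
README shows ≈0.15–0.19 at n = 30). This is a property of the estimator,
not a defect; the test suite asserts the direction of the bias, and
true-frequency GRMs recover the 0.25 expectation.

PCA operates on the GRM itself: the matrix is double-centered and
eigendecomposed; coordinates are eigenvectors scaled by the square root of
the non-negative eigenvalues, sorted by descending eigenvalue with ties
broken by original index. At full rank the coordinate Gram matrix
reconstructs the centered GRM exactly.

"Grouping similarity" — the agreement between PCA clustering and the
pedigree — has no standard definition; the declared surrogate is
nearest-centroid assignment in the top components (default 2), reported as
the fraction of individuals nearest their own family's centroid, ties
broken by family-id order and degenerate geometry flagged with a warning.
Family summaries report the mean and sample SD (n−1) over the C(n,2)
within-family pairs, with SD = 0 for a single pair and NaN means for
singleton families. Panel-versus-panel comparison uses the Pearson
correlation over the lower triangle including the diagonal (self
relatedness), matching how such comparisons are usually plotted; both the
diagonal flag and the SD convention are configurable.

## Pedigree correction

Two moves in fixed order. *Exclusion*: drop individuals whose maximum
off-diagonal relatedness to anyone falls below `unrelated_threshold`
(default 0.1) — sample mix-ups with off-pedigree material. *Reassignment*:
for each remaining individual, mean relatedness to every family's other
members; move to the best family when that mean reaches
`reassign_threshold` (default 0.125, half the half-sib expectation) and
exceeds the own-family mean by `margin` (default 0.1). Evaluation is a
single pass in id order against the pedigree as it stood on entry — no
cascading — so the output is a deterministic function of (GRM, pedigree,
config), and re-running on its own output makes no further moves in
simulation. All three thresholds are explicit, mandatory parameters: they
are declared surrogates centred on the 0.25 half-sib expectation, not
community standards, and sit close to the noise floor of small panels —
with ~1000 loci the unrelated-pair relatedness estimate has an SD of
about 0.033, so the maximum over a hundred such estimates approaches the
0.1 exclusion threshold often enough that genuinely unrelated samples are
occasionally retained (about one seed in eight in the planted-error
experiments). Larger panels or a higher threshold tighten this; the
defaults favour not excluding genuine material.

## In-silico PCR

Primer design replaces thermodynamic modelling with transparent,
deterministic rules: length 18–24 nt, GC 40–60%, Wallace-rule
Tm = 2(A+T) + 4(G+C) within [50, 72] °C (the window is wide because the
Wallace estimate scales with length: a 24-mer at 50% GC sits at 72),
homopolymer runs ≤ 4, footprints free of known SNPs and ambiguity codes,
product 100–150 bp containing the target SNP strictly between the
footprints. SNPs are selected at random (seeded) with a minimum spacing of
one maximum amplicon length, one pair per SNP, first valid candidate in a
fixed iteration order (ascending product length, then footprint
positions); per-SNP failure reasons are reported.

Matching is ungapped with an integer allowance of
floor(primer_length × pct / 100) mismatches — so the 10%-versus-0%
contrast is exactly two mismatches for a 20-mer and one for a 19-mer.
Template IUPAC codes match any compatible primer base without penalty,
since consensus references legitimately carry ambiguity codes. Amplimer
enumeration pairs every forward-strand hit of one primer with every
downstream reverse-strand hit of the other, tries both role assignments,
collapses duplicate spans, and caps products at 5000 bp (configurable);
products must be at least as long as the two primers. Coordinates are
1-based inclusive everywhere. Specificity is reported as the percentage
of pairs with exactly one amplimer across a template set; a second
template set gives cross-species transferability figures.

## Validation scope and problem sizes

The test suite validates each stage against independent oracles at desk
scale: hand-evaluated GRMs (3 individuals × 4 loci, checked to 10⁻¹⁰), a
hand-tallied 10-locus filter VCF violating one rule per locus, brute-force
sliding-window and all-pairs amplimer oracles on random templates up to a
few kb, binomial bounds on the observation layer, and the 0.25 half-sib
expectation on 20 families × 5 offspring × 1000 loci, where the
true-frequency GRM's grand within-family mean is required inside
0.25 ± 0.02. End-to-end runs are asserted byte-identical under a fixed
seed. `scripts/acceptance.py` recomputes the half-sib quantity from
scratch at the same design.

Passing these tests shows the algorithms are implemented correctly and
behave as theory predicts on data matching the generator's assumptions.
It does not demonstrate robustness to what the generator omits: indels
and alignment error, paralogous gene copies and reference bias (only
their depth/heterozygosity signatures are filterable), linked loci,
polyploid genotypes, population structure beyond the provenance level, or
caller-specific quality-score behaviour. Real-data percentages (filtered
SNP counts, amplification success on published genomes) depend on those
factors and on the genomes themselves, and are outside what synthetic
validation can reproduce.
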