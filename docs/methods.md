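# Methods

`famburden` implements a familial rare-variant discovery analysis for a
case–control design with multiplex pedigrees: a cohort of families each
contributing two or more sequenced affected members, a series of sporadic
(unselected) cases, and a large control series. The pipeline searches for
genes recurrently hit by rare protein-truncating variants in familial cases,
requires within-family co-segregation, aggregates evidence over gene sets,
and quantifies the design's detection power by simulation.

## Variant and genotype QC

Filtering proceeds genotype-first, then site-level, so site statistics are
always computed on post-mask data; the cascade is idempotent by
construction.

Genotype-level masks (a failing call becomes missing):

* genotype quality `GQ < 30`;
* heterozygote alternate read depth `< 3`;
* heterozygote allele balance: the 1-df goodness-of-fit statistic against
  an expected 50:50 read split, `(ad_ref − ad_alt)² / (ad_ref + ad_alt)`,
  at or above 10.83. (10.83 is the χ²₁ critical value for p = 0.001; the
  numeric cut-off is taken as authoritative.)

Site-level drops (each dropped site carries machine-readable reasons):

* upstream recalibration tranche failure (consumed as a boolean flag, never
  recomputed);
* 100-bp-window alignability below 1, or overlap with a simple repeat;
* call rate below 75% in cases or in controls, evaluated separately;
* exact-test Hardy–Weinberg p ≤ 1e-8 in cases or in controls. The HWE test
  is the exact conditional test (enumeration of heterozygote counts given
  the minor-allele count, summing tables at most as probable as the one
  observed) rather than the asymptotic χ², which is unstable at the rare
  frequencies this analysis lives at. It is validated against an
  exact-rational brute-force enumeration.

Qualifying variants are then the protein-truncating classes — nonsense,
splice acceptor/donor, frameshift — with minor allele frequency below 1%.
Missense variants are deliberately excluded: in-silico missense
pathogenicity prediction is not reliable enough to define qualifying
variants. Cohort MAF is the folded allele frequency over non-missing calls
of the full cohort; when a reference-panel frequency annotation is present
the larger of the two is compared with the 1% cut-off (which source the
threshold should use is genuinely open; max-of-both is the conservative
choice, and either alone can be obtained by omitting the other). Genes
whose qualifying variants are exclusively indels are removed, guarding
against indel-calling artefacts.

## Collapsing burden test and segregation

One sequenced affected member per pedigree is chosen uniformly at random as
the proband so pedigree members never contribute twice. The per-gene
statistic is the collapsed carrier count: a proband or control counts once
if it carries ≥1 qualifying variant in the gene, regardless of
multiplicity. Significance comes from permuting case/control labels over
probands + controls with group sizes preserved (default 10⁵ permutations),
with a one-sided enrichment tail and the add-one estimator
p = (1 + #{permuted ≥ observed}) / (n_perm + 1), which can never return 0.
Because the statistic under label permutation is exactly hypergeometric,
the implementation is cross-checked in two independent ways: an exhaustive
mode that enumerates every label assignment, and the closed-form
hypergeometric tail.

A note on calibration: the carrier count is a discrete statistic at rare
carrier frequencies, so valid permutation p-values are *super-uniform*
under the null — P(p ≤ α) ≤ α, typically well below α. Null-cohort
simulations therefore show rejection fractions clearly under the nominal
level; this is conservativeness, not miscalibration, and the test suite
asserts the one-sided property.

Effect size is the frequency-ratio odds ratio (a/n₁)/(b/n₂) — the ratio of
proband to control carrier frequency. Zero control carriers give an
infinite OR (flagged), with a half-count-corrected finite estimate
available. Genes are ranked by ascending permutation p, ties broken by
descending OR then symbol.

Segregation is strict: a variant segregates in a pedigree only when the
pedigree has ≥2 sequenced affected members and *all* of them carry it; a
gene segregates through any of its qualifying variants, and the candidate
filter requires segregation in at least two pedigrees. Sporadic cases are
held out of the familial test and used only in replication, where per-gene
carrier counts are compared against an external control table with a
two-sided Fisher exact test (scipy's hypergeometric summation, verified
against an exact-rational oracle).

## Pre-ranked gene-set enrichment

Genes are ranked by burden evidence with score −log₁₀(p_perm), ties broken
by OR then symbol. A set is scored by the running-sum (weighted
Kolmogorov–Smirnov) statistic: walking the list, hits increment by
|score|^w normalised by the set total, misses decrement by 1/(N − |S|); the
enrichment score is the signed maximum deviation, so ES ∈ [−1, 1].
Significance uses the pre-ranked convention — random same-size gene sets
drawn from the list — counting null sets whose |ES| reaches the observed
value with matching sign; multiplicity is controlled with
Benjamini–Hochberg q-values over testable sets.

The pipeline scores sets with w = 0 (the classical unweighted KS form) by
design: the burden-derived score is exactly 0 for every gene without a
case carrier, and with w = 1 such zero-score genes create two degeneracies
— a null draw containing one top gene padded with zero-score genes ties the
maximal ES, diluting a genuinely enriched set's p-value, and sets composed
entirely of zero-score genes are effectively scored by their arbitrary tie
order at the bottom of the list. The weighted form (w = 1 default at the
function level, any w ≥ 0) remains available for score distributions
without mass ties at zero.

## Power simulation

For each grid point (baseline carrier frequency f, relative risk RR), case
carriers are drawn Binomial(n_cases, f·RR) and control carriers
Binomial(n_controls, f); each of the 10,000 replicates is tested with a
two-sided Fisher exact test at exome-wide α = 8×10⁻⁷, and power is the
significant fraction, reported with its Monte-Carlo standard error
√(p(1−p)/n_reps). The default grid spans f ∈ [1e-5, 0.01] and
RR ∈ [1.75, 10]. "Frequency" is treated as a per-individual carrier
frequency (binomial per person rather than per allele); below 1% the
distinction from diploid allele sampling is negligible and the enumeration
oracle is simpler. When per-stratum enrichment applies (cases with one,
two or three affected first-degree relatives), the case frequency is the
weighted mixture Σ wᵢ·f·RRᵢ with Σ wᵢ = 1; no canonical weights exist, so
the default collapses to f·RR and weights are exposed in the configuration.

## Synthetic cohorts

The generator emits VCF + PED + GMT + cohort TSV + truth tables with the
cohort shape of the study design: 150 pedigrees with two sequenced affected
members (10% of families get a third, putting the familial case count near
twice the family count), 600 sporadic cases, 1,600 controls, 2,000 genes
with per-gene carrier frequency uniform on [0.0005, 0.005] split across a
Poisson number of variants (mean 3) whose consequence mix is half
protein-truncating. Planted risk genes add one dedicated nonsense variant
per designated family, generated as founder transmission conditioned
(importance-resampled) on full sharing among sequenced affected members,
plus an elevated sporadic-case frequency f·RR on the gene's background
variants. Competitor gene sets are drawn from non-risk genes so the
planted signal is concentrated in the designated set. QC violations are
injected orthogonally — each noisy site receives exactly one site-level
defect, each corrupted genotype cell exactly one genotype-level defect on
an otherwise clean site — so per-reason drop counts can be audited against
the truth table exactly. An all-heterozygote site is the HWE defect; the
truth table records which groups (cases/controls) it actually breaches at
the 1e-8 threshold, since the exact test only reaches that extreme with
roughly ≥35 genotypes in a group.

What the generator does *not* model: linkage disequilibrium and haplotype
structure, relatedness at null genes (genotypes there are independent per
individual, which leaves null carrier counts essentially unchanged),
population stratification, sequencing depth heterogeneity beyond the
injected defects, and realistic gene coordinates. Passing the recovery
tests therefore demonstrates the statistical machinery, not robustness to
confounding in real cohorts.

## Problem sizes used in the test suite

Simulation-based checks run at reduced scale chosen for statistical
resolution: type-I calibration uses 500 genes, 150 probands and 1,600
controls at 2,000 permutations; parameter recovery uses 60 families, 600
controls, 400 genes in 50 sets of 8 over 20 fixed seeds at 2,000
permutations for both the burden and set-level tests; the power oracle uses
a 20 vs 20 design at α = 0.05 where full Binomial×Binomial enumeration is
exact. Published odds ratios are recomputed at the study's actual sizes
(150 probands, 1,609 controls).

## Known limitations

* The burden permutation and GSEA nulls are marginal per gene/set; no
  joint exome-wide error control beyond BH is attempted.
* Replication assumes external control carrier counts are directly
  comparable (same qualifying-variant definition and coverage).
* The transcript-level reduction to one consequence per variant is assumed
  done upstream by the annotator.
* Kinship inference, covariate-adjusted burden models (e.g. SKAT) and
  ancestry adjustment are out of scope.
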