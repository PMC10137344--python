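# Methods

## Simulation model

**Genome.** The default genome is 10 autosomes of 1 Morgan carrying 500
equally spaced biallelic markers each (5,000 markers). Founder allele
frequencies are i.i.d. Uniform(0.05, 0.95); founders are drawn in
Hardy–Weinberg and linkage equilibrium (each haplotype allele an
independent Bernoulli draw at the marker's frequency). There is no
mutation, no sex chromosome and no genotyping error.

**Inheritance.** Meiosis follows the Haldane (no-interference) model.
Gametes are sampled at marker resolution: the haplotype of origin starts
uniformly per chromosome and switches between adjacent markers *d* Morgans
apart with probability (1 − e<sup>−2d</sup>)/2, independently across
intervals. Because only the parity of crossovers between observed markers
matters and Poisson counts in disjoint intervals are independent, this is
distributionally identical to simulating Poisson(Morgan-length) crossover
positions without interference, and it vectorises over whole cohorts. The
test suite checks the empirical recombinant fraction against Haldane's map
function at 10⁵ gametes.

**Traits.** Each trait draws its QTL positions without replacement
(disjoint between the two traits, so the combined objective spans 600
distinct loci under the defaults) and raw additive effects from a standard
normal. A single multiplicative calibration factor — one over the sample
standard deviation of the raw founder true breeding values — makes the
founder-population genetic variance exactly 1 by construction. True
breeding value is the additive score TBV<sub>i</sub> = Σ<sub>j</sub>
Z<sub>ij</sub> a<sub>j</sub> over the 0/1/2 dosages; it is the evaluation
criterion everywhere, including scenarios with non-additive gene action.

**Non-additive action.** A proportion *p* ∈ {0.1, 0.2, 0.3} of the QTLs
can receive dominance deviations (drawn standard normal, expressed at
heterozygotes) and/or round(*p*·n) disjoint additive×additive epistatic
pairs with effects on centred-dosage products. The *total* genotypic-value
variance is then recalibrated to 1 on the founders, so the additive share
of the unit variance shrinks as *p* grows — which is exactly why
similarity selection on additive ideals degrades in these scenarios.

**Phenotypes.** y = g + e with e ~ N(0, σ²<sub>g</sub>(1 − h²)/h²) and
h² = 0.5 by default (the heritability used for phenotype generation is a
free parameter of the design; 0.5 is a mid-range choice, exposed in the
configuration). Inside the breeding loop σ²<sub>g</sub> is fixed at the
founder-calibrated value (1 per trait) so the residual variance does not
shrink as selection depletes genetic variance; the standalone `phenotype`
function defaults to the sample variance of its input.

## Breeding design

Founders (200; equal sexes) split at random, balanced by sex, into lines A
and B of 100. Line A is selected for trait 1 (100 QTLs) and line B for
trait 2 (500 QTLs) — the natural order — each for 10 generations by
equal-weight similarity to its own trait's true ideal, 5 sires × 20 dams →
200 offspring (exact 1:1 sex ratio). Hybridization: F1 = 5 A sires × 20 B
dams; F2 = 5 B generation-10 males × 20 F1 females. Then five purebred
generations G1–G5. From the F1 cross onward, parents are chosen by the
selection method under test against the combined two-trait objective, and
every cohort is scored and truncation-selected; the recorded statistic is
the mean TBV of the selected males and females (whole-cohort means are
also emitted).

Selected parents are paired at random under a balanced scheme (equal dams
per sire, equal offspring per dam). Where the requested counts do not
divide — e.g. 200 offspring from 30 dams in the selection-proportion
scenarios — the remainder is spread as evenly as possible at random; the
low-level mating routine keeps strict divisibility as its default contract
and the breeding program opts into the near-balanced mode.

The foundation-scale scenarios vary the founder number and the
per-generation cohort size together over {100, 200, 500, 1000, 2000}. A
50-animal foundation is not representable: split into two 25-animal lines
it cannot supply 20 dams per line, so 100 is the smallest scale offered.

**Common random numbers.** All randomness flows from one master seed
through named substreams keyed by replicate and generation — never by
method — so the methods compared within a replicate share the genome,
trait architectures, founders, historical phase, tie-breaking and mating
randomness, and differ only through the selection scores. Scenario levels
that share the pre-cross design (e.g. pseudo-positive rates) also share
the simulated base state within a replicate, making level contrasts
paired.

## Selection criteria

**KIS.** The kinship index sums, over ideal loci, the locus weight times
the candidate's beneficial-allele dosage (0/1/2). Weights are 1
(equal-weight) or |calibrated additive effect| (effect-weighted). Ties are
broken by a seeded uniform draw, not id order, to avoid pedigree
artifacts. Perturbed ideals for robustness testing: false negatives drop
round(rate·L) loci through one seeded permutation, so deletion sets are
nested across rates; pseudo-positives add round(rate·L) loci, each the
nearest free marker to a random true locus (preferring index+1, then
index−1) with Bernoulli(1/2) beneficial alleles; the negative control is
600 no-effect loci with random beneficial alleles.

**GBLUP.** VanRaden method-1 GRM, G = WW′/(2Σp(1−p)) with W = Z − 2p at
the training set's observed frequencies (monomorphic markers excluded),
blended with 0.01·I for invertibility; single-trait animal-model
mixed-model equations with an overall mean as the only fixed effect and
the variance ratio λ = (1 − h²)/h² treated as known (no per-generation
REML at n = 200). Note that G centred at the observed frequencies is
exactly singular (G·1 = 0), which is why the blend is not optional in the
breeding loop.

**BayesB.** Per-marker effects are zero with probability π = 0.95 and
otherwise normal with marker-specific variances under a scaled-inverse-χ²
prior (df 4.234; scale set so the implied genetic variance matches
h²·var(y) given the observed heterozygosity). Full Gibbs sampling with
residual updates; default 2,000 iterations / 500 burn-in, shortened to
600/150 in the replicated comparisons (the posterior-mean EBVs used for
ranking stabilise much faster than the full posterior). The sequential
marker loop is compiled with numba. With π = 0 and fixed variances the
sampler collapses to SNP-BLUP, which the tests exploit as a cross-check;
GBLUP itself is checked against an independently coded ridge-regression
(SNP-BLUP) solver through the GBLUP/SNP-BLUP equivalence.

**Training data for the genomic methods.** Candidates are scored as
unphenotyped juveniles: their own records are masked and their EBVs flow
through genomic relationships to the phenotyped cohorts of a sliding
window (default: the three most recent cohorts, ≈ 400–1,200 animals).
This mirrors how genomic selection is actually deployed — selection
happens before the candidate's phenotype exists — and it is the regime the
method comparison is about: with candidate phenotypes included, GBLUP at
h² = 0.5 approaches mass selection plus family information and the
comparison degenerates. No reference population beyond the running
scenario exists, which is the small-population premise.

## Statistics

Per generation, a one-way ANOVA across methods (or scenario levels) on the
per-replicate means, Tukey-HSD pairwise comparisons at α = 0.05, and an
insert-and-absorb compact letter display (groups sharing a letter are not
significantly different; a zero-variance fallback compares means exactly).
Coefficients of variation are across-replicate sd/mean per method and
generation. Monotonicity across scenario gradients is assessed by the
endpoint difference of level means together with the mean within-replicate
regression slope across levels — a paired trend statistic; strict chains
of adjacent noisy means are uninformative when true differences between
neighbouring levels are near zero.

## Problem sizes used in the shipped checks

The packaged tests run the full base design (5,000 markers, 200 founders,
10 + 7 generations) with 5 common-random-number replicates for the
five-method comparison, 10 replicates for the cheap single-method
robustness gradients, 4 for the foundation-scale family, and 12 for the
negative control; BayesB uses the shortened 600/150 chains there. Unit
tests run on a 4 × 50-marker genome. The acceptance script averages the
founder-variance calibration over 10 replicate seeds.

## Known limitations

* The negative control's F1 value is statistically indistinguishable from
  its F2–G5 plateau here: under random selection the F1→F2 step equals a
  quarter of the between-line difference in historical gains (≈ +0.1σ in
  expectation) plus line drift (sd ≈ 0.7σ per replicate). A large F1 dip
  is not derivable from additive TBV accounting and is not reproduced.
* Founders start in linkage equilibrium; no historical LD burn-in is
  applied by default, so early-generation GBLUP accuracy leans on
  relationships rather than population LD.
* Absolute TBV levels are in founder-σ units with an arbitrary origin;
  only differences and trends are meaningful.
* No inbreeding control, overlapping generations, litter-size variation,
  maternal or environmental effects; selection and mating are
  within-cohort and sex-balanced by construction.
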