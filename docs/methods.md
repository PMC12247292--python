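# Methods

This note records the models implemented in `boacall`, the parameter
choices that matter, and what the synthetic validation does and does not
demonstrate.

## Founder simulation (`boacall.founders`)

Founders are sampled from a neutral coalescent split model in `msprime`:
an ancestral population (Ne = 1000) splits into an exotic branch and an
indigenous branch (Ne = 500); the indigenous branch later radiates into
four local breeds. Terminal breeds have Ne = 200, in line with the small
effective sizes of modern cattle breeds. Each of the five populations
contributes 500 diploid founders (2500 total).

The chromosome is 1 Morgan, mapped to 1 Mb of simulated sequence with a
uniform recombination rate; the mutation rate (1.2e-6/bp/gen under a
binary model) deliberately oversupplies segregating sites, from which
1000 biallelic SNPs with pooled minor-allele frequency >= 0.05 are
ascertained, evenly spaced along the chromosome.

The split times are not free knobs: they are fixed by calibration.
`calibrate_split` bisects the exotic split depth (local split scaled with
it at a 1:4 ratio) until the mean Hudson FST between exotic and pooled
local founders matches a target. The shipped defaults come from one
calibration against FST = 0.09 — the observed moderate differentiation
between exotic dairy and African indigenous cattle — giving a split depth
of 54 generations (local split 13.5). Re-simulation at these defaults
yields mean FST 0.087 (sd 0.007 over 20 seeds).

Randomness contract: every stochastic stage draws from an independent
stream keyed by (master seed, replicate index, stage), so replicates are
reproducible individually and order-independent.

## Breeding program (`boacall.breeding`)

The program mimics smallholder dairy crossbreeding:

1. The four local breeds are pooled (2000 animals) and mated at random
   for 10 discrete generations at constant size; the exotic breed is
   propagated in parallel (500/generation). Sex ratios are forced to
   one half.
2. A polygenic trait with mild directional dominance is sampled:
   100 QTL among the 1000 loci, additive effects a_i ~ N(0,1), dominance
   degrees delta_i ~ N(0.1, 0.1), d_i = delta_i |a_i|. The environmental
   variance is solved from the genic additive and dominance variances of
   the pooled local founders (linkage-equilibrium approximation) so the
   narrow-sense heritability there is 0.3. The 1000 phenotypically best
   cows become the foundation dams (a flag allows selection on true
   genetic value instead).
3. Five crossing rounds: each round imports 25 bulls drawn fresh from
   the contemporary exotic purebred generation; every dam calves twice
   with the sire drawn uniformly per mating (2000 calves, 1000 of each
   sex); all 1000 heifers replace their dams for the next round. No
   further selection is applied after the foundation cows.

Meiosis draws a Poisson(map length) crossover count with breakpoints
uniform on the genetic map (no interference) and cuts the haplotype pair
and the breed-origin pair at the same breakpoints from the same starting
chromatid. Purebred founders start with constant origin rows, so the
origin matrix of every descendant is exact identity-by-descent truth.
The expected exotic allele fraction in crossbred generation g is
1 - 2^-g, which the simulator recovers within Monte-Carlo error.

The QTL count (100) is a modeling choice — the trait drives a single
selection event and its genetic architecture beyond h2 and the dominance
distribution has no influence on the assignment benchmark.

## Windowing and phasing (`boacall.windows`)

Cores tile the chromosome contiguously; offset mode shortens the first
window to half a core so all later boundaries shift by 50%. Terminal
partial windows are kept, so every scheme covers each locus exactly once.
Default core lengths are 100–280 SNPs in steps of 20, both modes: 20
scenarios.

Statistical phasing is *not* reimplemented. The pipeline runs on true
simulated haplotypes by default; `inject_switch_errors` provides the
classic switch-error model (at each heterozygous site, with probability
r, maternal/paternal assignment flips from that site onward, genotypes
preserved) for sensitivity analysis. Consequences of this design are
discussed under Limitations.

## Assignment (`boacall.assign`) and consensus (`boacall.consensus`)

Libraries are the unique haplotypes of the purebred panels per core (the
local library pools all four local breeds). Matching is exact Hamming
distance, vectorized by de-duplicating target windows (bit-packing rows)
and computing distance matrices via the 0/1 inner-product identity in
float32 blocks; results are bit-exact equal to the scalar reference
implementation (property-tested). Observation counts are retained in
libraries but never used for tie-breaking: an equal best match in both
libraries is missing.

The optional `min_match_fraction` discards wins whose best match covers
less than the given fraction of the core. It defaults to off: the
operational threshold of the method is the consensus agreement threshold.

Consensus at threshold tau accepts the majority breed among non-missing
votes if it holds a strict majority and a share >= tau of them. Missing
votes are excluded from the denominator by default (the
`all_votes_denominator` flag implements the stricter reading). Threshold
comparisons use a 1e-9 guard so that an exact boundary share (e.g. 11/20
at tau = 0.55) is accepted regardless of float rounding; assignment is
then exactly monotone: every allele assigned at a stricter threshold is
assigned identically at every looser one.

For evaluation, crossbred round r is assigned against the purebred
cohorts of its parental generation — the panels that contain the actual
imported bulls, matching how contemporary reference panels would be
genotyped in practice.

## Metrics (`boacall.metrics`)

%correct / %incorrect / %unassigned share the stratum's full allele-cell
denominator and sum to 100 exactly (the unassigned percentage is computed
as the complement). Accuracy over an empty assigned set is reported as
missing, never 0 or 1. FST defaults to Hudson's ratio-of-averages
estimator on allele frequencies (monomorphic loci excluded); a
Weir–Cockerham ANOVA variant is available behind a flag. PCA is plain
SVD of the column-centered dosage matrix.

## Problem sizes used in tests and the acceptance script

The shipped evaluation runs 10 replicates of the full design (2500
founders, 1000 SNPs, 10 generations of premixing, 5 crossing rounds of
2000 calves, 20 windowing scenarios, 10 thresholds), about 3–4 minutes on
one CPU. Unit and property tests use miniature instances (20–30
individuals per population, 100–200 SNPs) that exercise identical code
paths.

## Limitations

* **Phasing fidelity is emulated, not modeled.** Real pipelines phase
  statistically; phasing failure and switch errors add missing and wrong
  assignments. With true haplotypes the only source of missingness is a
  library tie (~0.3% of alleles at these panel sizes), which is an
  optimistic lower bound. In particular, the level of unassigned alleles
  and its trend across crossbred generations reported from
  phaser-dependent pipelines are not reproduced here: in this simulator
  the first crossbred generation is the *easiest* to assign (its gametes
  are one meiosis away from panel haplotypes), and yield stays near
  0.996–0.998 across generations instead of climbing from ~0.95. The
  switch-error injector lets users probe this sensitivity explicitly.
* Incorrect assignments are concentrated at cores straddling an ancestry
  switch point, where a single call is broadcast over loci of two
  origins; the consensus stage, whose staggered windows disagree exactly
  there, removes most of them (consensus %incorrect 0.07 at tau = 0.95).
* The demography is a stylized two-level split calibrated only to the
  exotic-vs-local FST; real African admixed populations carry deeper
  Taurine/Indicine structure that a single FST summary does not capture.
* One chromosome, uniform map, no interference, discrete generations, no
  inbreeding management or genomic selection of bulls.
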