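# Methods

`sweepscan` implements a two-step genome scan for artificial selection in
domesticated populations genotyped on a dense SNP array, together with a
forward simulator that generates data with known injected sweeps so every
stage can be exercised and validated without access to real array data.

## The two-step scan

**Step 1 — positive selection within a domestic pool.** Two complementary
statistics are computed on the phased haplotypes of each domestic pool:

* *Windowed unstandardized |iHS|.* At a core SNP, the extended haplotype
  homozygosity (EHH) of an allele at a flanking marker is the probability
  that two random carrier haplotypes are identical at every marker from
  the core to that marker. Each side of the curve is extended until EHH
  falls below 0.05 (configurable) or a 1 Mb guard is reached, and
  integrated over physical distance by the trapezoid rule; segments whose
  far endpoint is below the cutoff are discarded. The score is
  iHS = ln(iHH_A / iHH_D). No frequency-bin standardization is applied —
  significance comes from a permutation threshold, not from a
  standard-normal reference — so |iHS| is simply averaged in
  non-overlapping 10 kb windows (cores need MAF ≥ 0.05 and ≥ 2 carriers
  per allele). Integration is over base pairs because array data carry no
  genetic map; iHS values are therefore comparable within a dataset but
  not across maps.

* *Composite likelihood ratio (CLR).* The genome-wide unfolded site
  frequency spectrum φ(k) over derived counts k = 1..n−1 is the background
  model. Around a putative completed sweep at grid point g, a lineage at
  distance d escapes the sweep with probability p_e(d) = 1 − exp(−α d)
  (star-like approximation); e ~ Binomial(n, p_e) lineages escape, the
  escapees plus one founder are a hypergeometric subsample of the
  background, and the founder's allele is copied into the n − e swept
  lineages. CLR(g) = 2[max_α Σ ln P(k_i | α, d_i) − Σ ln φ(k_i)],
  maximized over a 64-point log-spaced α lattice (spanning p_e(10 kb)
  from 0.001 to 0.999) with golden-section refinement; ties resolve to the
  smaller α, and the α→∞ (background) model is always a candidate, so
  CLR ≥ 0. Sites at counts 0 and n are excluded from the background
  (arrays have no invariant sites); the model vector is renormalized over
  1..n−1 when scoring observed sites. Grid points sit at 10 kb window
  midpoints and use sites within a 100 kb flank (configurable). For
  speed the per-count log-likelihood is tabulated on a 2048-point
  Chebyshev-spaced p_e grid and interpolated linearly; the table is exact
  at its nodes and the interpolation error is far below the optimizer's
  tolerance.

**Step 2 — differentiation against the wild reference.** Weir–Cockerham
variance components (a, b, c) are computed per site between the domestic
pool and the wild reference pool, with genotypes reconstructed from
consecutive haplotype pairs. Window F_ST is the ratio of sums
Σa / Σ(a+b+c) over the window's sites — standard multi-locus practice;
per-site negative components are retained. Observed heterozygosity
(fraction of heterozygous individuals, averaged per window) and
major-allele-frequency tracks accompany the scan.

**Thresholds and regions.** Each statistic gets an empirical 5% threshold
from permutations (1,000 by default): F_ST permutes individual pool labels
between the two pools; |iHS| permutes per-site scores across positions
genome-wide; CLR permutes derived counts within each chromosome and
re-runs the grid scan (100 permutations by default for runtime,
overridable). All permuted window values pool into one null; the threshold
is its 95th linear-interpolation percentile and outliers are windows
strictly above it. Each outlier window's midpoint ± 100 kb becomes a
potential selection region; same-method regions merge when they touch, iHS
and CLR regions merge when separated by ≤ 200 kb (iHS-CLR), and an iHS-CLR
region overlapping an F_ST region by ≥ 1 bp is retained — in full extent —
as an artificial-selection region.

The label-permutation F_ST null tests *exchangeability of individuals*
between the two pools. On pools that have genuinely drifted apart it
rightly flags genome-wide divergence; its nominal 5% calibration is
therefore checked on two pools sampled from one undivided population
(no post-split drift), which is the null hypothesis the permutation
embodies.

**Hard/soft classification.** Inside each artificial-selection region,
haplotype blocks are inferred by the solid-spine-of-LD rule (first and
last marker each with |D′| ≥ 0.8 against every intermediate marker),
greedily left to right preferring longer spans. D′ comes from the pooled
haplotypes of *all* domestic pools, so an allele fixed in the observed
pool is still polymorphic in the spine matrix; markers monomorphic in the
spine matrix are excluded from block inference rather than breaking
blocks. Blocks are capped at 50 kb: on pooled differentiated pools |D′|
stays high at arbitrary distance (admixture LD), and an uncapped spine
fuses entire regions into blocks whose haplotype strings are too long to
retain meaningful frequencies; 50 kb is the scale over which
within-population LD decays both in the simulations and on dense chicken
arrays. A block haplotype with frequency > 0.8 in the observed domestic
pool is a core haplotype; its exact string frequency in the reference
pool classifies the sweep: 0 → hard (de novo allele), > 0.125 → soft
(standing variation, ≥ 4 of 32 reference gametes), (0, 0.125] →
unclassified. A region with several blocks is hard if any core is hard,
else soft if any is soft.

## Quality control and coding

Individuals below 95% call rate are removed first; SNPs then fail on call
rate ≤ 99%, per-breed Hardy–Weinberg exact test (Wigginton-style
enumeration; a SNP failing p ≤ 1e-6 in any one breed is removed
globally), minor allele frequency ≤ 1%, or non-autosomal location. The
ancestral allele is defined as the reference-pool major allele (the wild
pool proxies the ancestral population; ties keep the current 0 allele),
and the same unfolded coding feeds both iHS and the CLR spectrum; a
folded-spectrum mode exists for when the ancestral proxy is distrusted.
Input must be phased and complete; an optional per-pool major-allele fill
handles stray missing calls, but imputation is out of scope.

## The synthetic-data generator

A discrete-generation diploid Wright–Fisher model on a lattice of
candidate SNP positions along one chromosome. Gametes recombine with a
Poisson number of uniformly placed crossovers (rate 1e-7 /bp/gen, giving
an LD half-decay of a few tens of kb at the default population size);
sites mutate recurrently between their two alleles at mu = 1e-5. Standing
variation is initialised from Beta(0.2, 0.2) frequencies truncated at
MAF > 0.05 — an array panel targets variants common at design time — and
a 300-generation burn-in builds LD. At the split each pool founds from a
disjoint sample of the ancestral diploids; the wild population persists
at five times the ancestral size (a wild reference is a small *sample* of
a large population) and the reference pool is sampled from it at output.
Selection is genic (1, 1+s, 1+2s), applied only in the domestic pool a
sweep targets. Hard sweeps zero the chosen site everywhere and introduce
the allele on one haplotype (reference frequency exactly 0 by
construction); soft sweeps select a standing variant whose ancestral
frequency is within ±0.05 of f0. A pool whose beneficial allele is lost
restarts from the split state (bounded retries). Output keeps only sites
with combined-sample MAF > 0.01, mimicking array ascertainment, and a
fixed seed makes every byte reproducible.

Default study conditions: 100 ancestral diploids, 2 pools of 50, 10 Mb,
~3,200 retained SNPs, 50 post-split generations (roughly a century of
breed improvement at observed chicken generation times) and s = 0.3 —
strong, recent artificial selection whose sweeps approach fixation within
the split time. Soft sweeps default to f0 = 0.25: standing variants picked
up by breeding programmes are common ones, and the value leaves principled
clearance above the 0.125 classification floor after the ±0.05
conditioning tolerance and haplotype decay in the reference.

What the generator does *not* emulate: real recombination-map structure
and hotspots, multi-chromosome pedigree sharing, ascertainment bias
toward specific breeds, genotyping error, migration or admixture between
breeds, and background selection. Passing recovery tests therefore shows
the pipeline's statistics behave as designed under a clean
Wright–Fisher sweep model, not that their power on real array data is as
high.

## Calibration and recovery experiments

* *Threshold calibration.* Two pools of 50 diploids are sampled from one
  ancestral population of 300, over ten freely recombining chromosomes
  (~950 windows, ~3,000 SNPs). The 5% threshold is derived from 1,000
  label permutations on one replicate and applied to an independent
  replicate; the flagged fraction is expected at the nominal level within
  binomial error. The design choices matter: with a small ancestral
  population, kinship fluctuations between the two samples shift the
  genome-wide F_ST level coherently, and with strong LD adjacent windows
  exceed the threshold together — either way the flagged fraction becomes
  far more variable than the binomial yardstick presumes. Sampling 100 of
  300 diploids and keeping windows effectively unlinked restores the
  independence the error bar assumes (measured: mean 0.050, sd 0.005
  across seed pairs).
* *Parameter recovery.* Over 20 seeded replicates per mode (2 Mb, three
  pools, sweep at the chromosome midpoint), the true sweep region is
  classified hard for hard injections and soft for soft injections in the
  large majority of replicates; a scaled-down full-scan experiment checks
  that the artificial-selection region set covers the injected position.

## Numerical choices and edge cases

* Windows tile from position 1; position 10,000 belongs to window 0.
  Intervals are 0-based half-open internally, 1-based in VCF I/O.
* Strict ">" at thresholds and at the 0.8 / 0.125 classification cutoffs;
  quantiles use linear interpolation.
* EHH cores with < 2 carriers of either allele, or with a vanishing
  integral, are skipped and logged.
* Sites monomorphic across the union of two pools are excluded from
  F_ST; sites monomorphic in only one pool are kept.
* Ancestral-coding ties (reference frequency exactly 0.5) keep allele 0,
  so recoding is idempotent.
* The rounding of reported percentages is decimal half-up (2 decimals per
  pool; integer / one decimal for the cross-pool means of counts /
  lengths) to match conventional reporting.

## Known limitations

* The pipeline requires phased, essentially complete genotypes; phasing
  and imputation quality are upstream concerns.
* Unstandardized |iHS| window means are sensitive to local SNP density;
  the positional-permutation null accounts for the score distribution but
  not for density gradients.
* The CLR model is the star-like approximation with physical distance as
  a proxy for recombination distance; α is per-bp and not comparable
  across genomes with different map rates.
* On strongly drifted pools the F_ST exchangeability null flags much of
  the genome; the two-step intersection, not the F_ST test alone, carries
  the specificity.
* Hard/soft classification depends on the swept core being representable
  by a block haplotype; sweeps fixed across *all* domestic pools leave no
  polymorphism for block inference and fall back to "unclassified".
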