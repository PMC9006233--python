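# Methods

`streampop` models the population-genetic consequences of small in-stream
barriers (weirs, culverts) for strictly aquatic macroinvertebrates living in
linear stream networks, and provides the statistic stack needed to analyze
both simulated and empirical SNP matrices.  This note documents the models,
the estimators, the numerical choices, and the limits of what the synthetic
data can show.

## The forward-time metapopulation model

A stream is a line of `n_demes` demes ordered from the most upstream (index
0) to the most downstream.  Generations are discrete and non-overlapping;
one generation is treated as one year, which for the motivating taxa
(amphipods, freshwater snails, flatworms with 1–3 year life cycles) is a
deliberate simplification — real generation counts may be lower than
elapsed years.

Each generation runs four steps:

1. **Extinction pressure** on adults, before breeding.  Two models:
   * `proportion` (default): every deme independently loses a
     Binomial(n, e) share of its adults.  Demes stay occupied; the
     per-generation bottleneck cuts effective size roughly by the factor
     (1 − e), which reproduces the empirical signature of local extinction
     pressure — faster drift, higher F_ST, faster erosion of diversity —
     while keeping every deme observable at every census.  This is the
     model used for the study conditions, because whole-deme extinction at
     e = 0.6 per generation leaves each deme empty at roughly half of all
     censuses, which is incompatible with evaluating four fixed populations
     at fixed time points (and, with six demes, destroys the whole
     metapopulation within tens of generations with near certainty).
   * `patch`: the classic extinction–recolonization alternative — a deme is
     emptied outright with probability e and is repopulated only by
     dispersing offspring (possibly in the same generation).  Draws are
     conditioned on metapopulation persistence: a draw that would empty
     every occupied deme spares one uniformly chosen deme, since a globally
     extinct run has nothing left to analyze.
2. **Reproduction.**  Every occupied deme produces exactly `K` offspring
   (patch capacity = fecundity target).  `random_mating` draws each
   offspring's two parents uniformly with replacement (Wright–Fisher,
   N_e ≈ K — verified against the closed form below).  `hermaphrodite`
   selfs with probability `s` and otherwise takes two distinct parents; a
   deme of one individual must self.  Each transmitted allele flips with
   probability `mu` (two-allele mutation model, default 1e-4 — enough to
   keep variation from eroding completely over 250 generations at small K,
   negligible on the barrier-detection time scale).
3. **Dispersal.**  Offspring move only to adjacent demes.  The preset
   `asymmetric15` sends 15% of offspring downstream and 5% upstream per
   generation (flow-biased 3:1); `symmetric10` sends 10% each way.  At the
   ends the blocked direction's probability mass is added to staying.
4. **Regulation.**  Demes above `K` are down-sampled uniformly.  Census
   sizes therefore never exceed K but fluctuate binomially below it
   (systematically so at the end demes, which receive less immigration);
   this is why analysis-time sampling drops demes that fall below the
   requested sample size.

**Barriers** act on a single edge from generation `t_b + 1` (default: after
a 100-generation burn-in that separates dispersal-model structure from
barrier effects).  Three models: `complete` (both directions blocked),
`upstream_block` (upstream crossing blocked, downstream untouched) and
`upstream_block_reduced_down` (upstream blocked, downstream set to the
absolute per-generation probability `residual_down`, e.g. 0.01).  Removed
mass goes to the stay probability.  The default edge is between the 3rd and
4th of six demes, mirroring a sampling design with two analyzed sites on
each side of the barrier and one unanalyzed edge deme at each end to absorb
boundary effects.

Loci are unlinked biallelic SNPs stored as reference dosage; initial
frequencies are drawn once per locus from Uniform(0.1, 0.9) and shared by
all demes (a common ancestral pool), so all differentiation is generated by
the dynamics.  The default panel is 500 loci.  Everything is a
deterministic function of the seed.

### Physics checks

Two closed forms anchor the simulator:

* **Drift.**  For two isolated demes of capacity K with mu = 0, mean
  Weir–Cockerham theta follows 1 − (1 − 1/(2K))^t (verified at K = 50 over
  50 replicates to within 0.02–0.04 absolute).
* **Migration–drift equilibrium.**  For symmetric dispersal the island
  model predicts theta ≈ 1/(1 + 4K m̄).  The relevant m̄ for a linear array
  is its realized mean emigration rate, `mean(1 − diag)` — the two end
  demes emigrate at half the interior rate — giving m̄ = 1/6 for
  `symmetric10` with six demes.  One-dimensional stepping-stone geometry
  concentrates exchange in neighbors, so the mean pairwise theta sits near
  the top of a factor-two band around this prediction; the test asserts
  that band.

## Summary statistics

All estimators are frequency-based and handle missing data per locus with
the typed gene-copy counts of each population.

* **H_O** — fraction of heterozygotes among typed individuals.
* **H_S** — unbiased within-population gene diversity
  `2n/(2n−1) · 2pq` per locus, averaged over populations.
* **H_T** — total gene diversity `2 p̄ q̄` from the *unweighted* mean of
  population frequencies, deliberately without a sample-size correction;
  H_S ≤ H_T therefore holds only up to the `2n/(2n−1)` correction.
* **F_IS** = 1 − H_O/H_S from across-locus means; undefined (NaN) when
  H_S = 0.
* **Weir–Cockerham theta** — the two-allele variance-component estimator;
  multi-locus values are ratios of component sums, loci typed in fewer than
  two populations (or with mean sample size ≤ 1) are dropped, and negative
  estimates are reported as-is.  Significance of differentiation is defined
  throughout as the bootstrap-over-loci 95% percentile interval (default
  10,000 replicates, 0.025/0.975 quantiles) excluding zero from below.
* **Nei's G_ST** = (H_T − H_S)/H_T from frequencies alone, equal population
  weights, no sample-size correction; multi-locus via sums over loci; the
  all-monomorphic case is defined as 0.
* **Allelic richness** — hypergeometric rarefaction to `g` gene copies,
  `AR = Σ_a [1 − C(N−N_a, g)/C(N, g)]`, computed with log-gamma binomials;
  default `g` is the smallest typed gene-copy count over population × locus
  cells; cells with fewer than `g` copies are excluded from means.
* **Private alleles** — alleles present in exactly one population, counted
  after subsampling every population without replacement to the smallest
  population size (default 30 replicates); with equal sizes the replicates
  are identical by construction.
* **Mantel test** — Pearson correlation of lower-triangle distances with a
  label-permutation p-value `(count ≥ observed + 1)/(n_perm + 1)`;
  one-sided (positive association) with 9,999 permutations by default.
  Zero-variance distance matrices are rejected rather than returning an
  undefined r.

Locus filters run in a fixed, reported order — one-SNP-per-RAD-locus (when
locus ids carry a group key), per-population presence, overall presence,
pooled minor allele frequency — because the order affects MAF denominators
marginally and reproducibility requires it be pinned.  MAF is computed on
calls pooled over all individuals.

## Directional relative migration

For an ordered pair (i, j) a hypothetical migrant pool is formed with the
unweighted mean of the two populations' allele frequencies, and Nei's G_ST
between the *recipient* and the pool measures how far the recipient has
diverged from the shared migrant gene pool: a population receiving many
migrants resembles the pool, so low differentiation from the pool implies
high immigration.  Differentiation d maps to an effective-migrant scale via
Nm = ((1/d) − 1)/4, with d floored at 1e-6 so undifferentiated pairs
saturate at the maximum instead of dividing by zero; the directed matrix is
then divided by its maximum, making the largest rate exactly 1.  Bootstrap
intervals resample loci (1,000 replicates by default for networks), with
each replicate re-normalized by its own maximum; asymmetry of a pair is
called significant when the two directions' intervals do not overlap.  The
resampling unit (loci) matches the F_ST machinery for internal consistency.

A caution inherited from the underlying method: in simulations with
flow-biased dispersal the *direction* of asymmetry is not reliably
recovered, so direction calls should be treated as descriptive; the
*reduction* of cross-barrier rates after barrier introduction is the robust
signal, and that is what the experiment pipeline tests.

## The barrier-effect experiment

`detect_barrier_effect` operationalizes "consistently higher cross-barrier
differentiation": at a post-barrier snapshot the effect is detected when
(a) every cross-barrier pair is CI-significant, (b) the smallest
cross-barrier estimate exceeds the largest reference (same-side) estimate,
and (c) both conditions persist for the next two snapshots (window
configurable).  The detection generation is reported relative to barrier
introduction and is a multiple of the snapshot interval.  The
reference/cross pair layout is always explicit input, never inferred from
labels.  Analysis sampling takes 10 individuals per deme per snapshot
(edge demes excluded, demes below the sample size dropped), so the
detection latency includes realistic resampling noise.

With this rule, detection latency under a complete barrier behaves as drift
predicts: a few generations at K = 100, longer at large K.  At K = 2000
with the default 500-locus panel the per-snapshot standard error of a
pairwise theta (n = 10 per population) is about 0.002, so all four
cross-barrier pairs only become simultaneously significant once theta
reaches roughly 0.005–0.008, i.e. some 50–100 generations post-barrier;
larger locus panels shorten this latency roughly with the square root of
the panel size.

`divmigrate_timepoints` evaluates networks at fixed generations (default
5, 50, 95 pre-barrier and 110, 150, 200, 250 post-barrier) and flags a
reduction when every evaluable directed cross-barrier rate falls below the
minimum the same edge showed pre-barrier; edges involving demes excluded at
a time point are skipped, and a time point with no evaluable cross edge
yields a NaN verdict rather than a detection.

`run_grid` sweeps scenario cells (K × mating/selfing × extinction ×
dispersal × barrier model) with deterministic per-replicate seeds derived
from a base seed, writes one long-format row per statistic, and records
failures without aborting the grid; cells already written to the output
directory are skipped on re-run.

## Synthetic empirical data

`generate_stream_dataset` builds ddRAD-like SNP matrices with a two-level
Balding–Nichols hierarchy: per locus an ancestral frequency p0 ~
Uniform(0.1, 0.9); per stream a Beta draw with mean p0 and variance
F_stream·p0(1−p0); per site within a stream another Beta draw around the
stream frequency with parameter F_site; genotypes Binomial(2, p_site);
missingness completely at random.  The closed-form F parameters enable
estimator-recovery tests: a Monte-Carlo oracle of the Weir–Cockerham
estimator under the model confirms that the mean pairwise theta between two
sites recovers F_site to within ±0.02 at 2,000 loci.

What the generator does *not* emulate, and what passing tests therefore do
not show about real data: linkage of SNPs within RAD loci, structured
missingness (real ddRAD missingness concentrates in low-quality individuals
and loci, so a flat 10% MCAR rate makes a 95% overall-presence filter
reject nearly all loci — with real data the same filter is mild),
polyploidy and allele-dosage ambiguity, and isolation-by-distance gradients
within streams.  The fixed preset (4 streams × 4 sites × 10 individuals,
1,500 loci, F_stream = 0.3, F_site = 0.02, 10% missingness) mirrors the
magnitude of between-stream versus within-stream differentiation seen in
regional stream-invertebrate surveys.

## Numerical and design notes

* FSTAT I/O uses one-digit allele codes (loci are biallelic; header
  `np nl 2 1`), code 1 = reference, all-zero code = missing; input
  auto-detects the digit width from the header.  The format stores neither
  individual ids nor population names, so reading normalizes labels to
  `pop<k>`; write/read roundtrips are exact for matrices in that canonical
  form.
* Bootstrap, subsampling, permutation and simulation randomness all flow
  from explicit seeds through `numpy.random.default_rng`; identical seeds
  give bit-identical results.
* Rarefaction binomial coefficients are computed in log space; ratios are
  exponentiated only at the end, so N up to thousands of gene copies is
  safe.
* Problem sizes used by the acceptance script and heavy tests — 5–10
  replicates, 500 loci, 1,000 bootstrap replicates, capacities up to
  2,000 — were chosen to keep a full recomputation on a single CPU in the
  tens of minutes while leaving the Monte-Carlo error well inside the
  tolerances tested.
* Known limitations: no selection, no age structure, no within-generation
  density dependence beyond the K cap, generations equated with years, and
  the extinction-model caveats discussed above.
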