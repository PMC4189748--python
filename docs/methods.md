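# Methods

This note documents the models, estimators and numerical choices behind
`imabc`, in the spirit of the methods documentation of coalescent and
statistical packages: what is computed, under which assumptions, with
which defaults, and where the behaviour is a deliberate design choice.

## The IM model and its simulator

The demographic model is the two-population Isolation-with-Migration
model: an ancestral Wright–Fisher population of constant effective size
`N_A` splits `t` generations before the present into population 1
(founding effective size `s * N_A`) and population 2 (founding size
`(1 - s) * N_A`). Between the split and the present each descendant
population's size interpolates exponentially from its founding size to
its present size (`N1`, `N2`); the ancestral population is constant.
Migration acts while both descendant populations exist.

**Migration convention.** `m1` is the *backward-in-time* per-generation
probability that a lineage currently in population 1 traces its ancestry
into population 2 (equivalently, the forward rate at which individuals
from population 2 enter population 1), and symmetrically for `m2`. This
matches the convention of structured-coalescent software generally; it is
stated prominently because model diagrams usually leave the direction
ambiguous.

**Simulation.** The simulator works backward in time on lineages carrying
leaf-set bitmasks. Within the growth phase the pair-coalescence hazard in
population *i* is `k(k-1) / (4 N_i(tau))` with
`N_i(tau) = N_i * exp(beta_i * tau)` and
`beta_i = ln(founding / present) / t_gen`; waiting times are drawn by
inverting the cumulative hazard in closed form, so there is no time
discretisation or generation stepping anywhere. Coalescence in either
population and migration events are competing independent exponential
clocks; at the split all surviving lineages merge into the constant-size
ancestral population. Sample sizes larger than the (census-like) effective
size are legitimate under the coalescent and accepted.

**Mutation.** Infinite sites on a finite locus: the number of mutations is
Poisson with mean (total branch length in generations) × (whole-locus
per-generation rate); each mutation lands on a branch with probability
proportional to its length, at a position drawn uniformly on the locus and
discretised to an integer coordinate, redrawing on collision. Simulated
matrices are derived-allele coded; all shipped statistics are
fold-invariant, so this never conflicts with the major-allele convention
of the file readers.

**Recombination** (used by the ABC_rec variant) is a deliberately simple
multi-tree approximation: breakpoints arrive along the locus as a Poisson
process with intensity `rho_per_locus ×` (current tree length), and each
segment receives a freshly simulated, *independent* genealogy. Adjacent
trees are therefore uncorrelated, unlike in an ancestral recombination
graph or an SMC, which overstates the decay of linkage within a locus.
This is acceptable here because the inference target is robust to the
recombination treatment (analyses with and without recombination give
concordant estimates on data of this size); every simulated matrix records
which scheme produced it (`recombination_scheme` attribute).

**Correctness evidence.** The test suite checks the single-population
limit against Watterson's `E[S] = theta * a_n` and `E[pi] = theta` at 10⁴
replicates, the no-recombination four-gamete guarantee over 500 loci, and
the full IM configuration (growth + asymmetric migration + split) against
msprime via a two-sample KS test on the distribution of S — msprime serves
purely as an independent oracle, never as the implementation.

## Scaling

Inference operates on `theta = 4 * Ne * mu` (per locus), `T = t * mu`
(per year) and `M_i = m_i / mu` (per generation). The multilocus `mu` is
the geometric mean of the per-locus rates; the default rate model is
1.47e-6 per locus per year with 25 years per generation (3.675e-5, printed
as 3.68e-5, per generation). Time-like quantities convert through the
per-year rate, population sizes and migration through the per-generation
rate; both are exposed because the two scales are routinely mixed in this
literature. Round-trips between scaled and demographic parameterisations
are exact to ~1e-12 relative.

## Four-gamete filtering

Under infinite sites, two biallelic sites displaying all four gametes
(00, 01, 10, 11) cannot descend from a single non-recombining genealogy.
`filter_recombination` extracts a violation-free subset of a haplotype
matrix:

* **exact mode** (default up to 12 × 12): enumerate row subsets in
  decreasing size with a cell-count bound; for each, the compatible site
  sets form an independent-set problem on the pairwise-conflict graph,
  solved exactly by branch and bound. The objective is retained data
  cells (rows kept × sites kept).
* **greedy mode** (beyond, or on request): iteratively remove the row or
  site with the highest violation participation per unit cost. A site's
  participation is the number of active violating pairs containing it; a
  row's is the number of pairs in which it carries a minimum-count gamete
  class (removing such rows is what can actually break a pair). The cost
  of a removal is the number of data cells it discards times a
  configurable weight, which automatically prefers dropping sites when the
  matrix is wider than tall — i.e. prefers keeping sequences, matching how
  such filters are used in practice. Ties prefer rows, then the lowest
  index, making the procedure deterministic.

Calibration: over random 10 × 8 matrices the greedy solution retains on
average ≥ 90% (typically ~94%) of the exhaustive optimum's cells, and its
output is always violation-free and idempotent. Columns rendered
monomorphic by row removal are retained data but dropped from the returned
matrix (they carry no polymorphism) and listed in the report.
`segment_split` additionally supports discarding the worse half of a locus
at the internal boundary with the fewest spanning violations, for the
common case of recombination concentrated in one locus segment.

## Summary statistics

Per locus and population: segregating sites S, nucleotide diversity pi
(mean pairwise differences per locus), number of distinct haplotypes K,
and Tajima's D (standard variance normalisation; undefined when S = 0 or
n < 4). Per locus across populations: pooled S and Hudson's
F<sub>ST</sub> = 1 − Hw/Hb (undefined when Hb = 0). Across loci the
vector records means and standard deviations, the four site-sharing
counts (shared / private-1 / private-2 / fixed; they always sum to the
total segregating sites) and mean F<sub>ST</sub>. Undefined per-locus
values are *excluded* from means/SDs rather than zero-imputed — zero
imputation would bias ABC distances — and exclusion counts are reported.

**The ABC distance uses a 14-component default subset**: the across-locus
means (not SDs) per population, pooled mean S, the four sharing counts and
mean F<sub>ST</sub>. The across-locus SDs are computed and can be added,
but with ~100 retained draws the extra dimensions degrade the local-linear
adjustment (more regressors than the retained sample can support) more
than they inform the distance; POD calibration confirmed materially better
HPD coverage with the 14-component set. The set is a configurable argument
throughout, so a different published statistic list can be swapped in
verbatim.

## ABC engine

* **Priors:** independent uniforms, by default theta_i in (0, 5), T in
  (0, 0.05), M_i in (0, 10), s in (0, 1); the recombination variant adds a
  log-uniform per-locus rate. Demographic priors are induced from these
  through the rate model.
* **Standardization:** each statistic is scaled by its median absolute
  deviation over the full simulation table (SD fallback when the MAD is
  zero; constant statistics are dropped) — robust scaling in the
  ABCToolBox tradition. Simulated rows with undefined entries in a used
  statistic receive infinite distance and can never be retained.
* **Rejection:** Euclidean distance on standardized statistics; retain the
  `ceil(retention × n)` closest rows (default 1%), ties broken by row
  order; reproducible by an independent full sort.
* **Regression adjustment:** Epanechnikov weights
  `1 − (d/δ)²` with bandwidth δ = largest retained distance, weighted
  least squares of each transformed parameter on the standardized
  statistic discrepancies, adjusted draw = fit at the observation plus
  residual. Parameters with finite prior bounds are interval-logit
  transformed before regression — a one-sided log would respect only the
  lower bound, and the adjustment must never move a draw outside the prior
  support. A singular fit falls back to the unadjusted draws with a
  warning.
* **Summaries:** weighted Gaussian KDE on a 512-point grid over the prior
  range, with *boundary reflection* at finite support edges (an
  edge-truncated KDE loses mass at hard prior boundaries and biases HPDs
  inward). The density/HPD bandwidth is Silverman's rule on the weighted
  sample (effective sample size `(Σw)²/Σw²`); the *mode* is read from a
  second pass with bandwidth `1.5 × spread × neff^(-1/7)` because the
  argmax of a density estimate is noisier than the density itself and its
  optimal bandwidth shrinks as n^(-1/7), not n^(-1/5). The 90% HPD is the
  smallest density-ordered grid-cell set of mass 0.90, reported as its
  enclosing interval (for a flat density any 90% set qualifies, so the
  reported interval can legitimately approach the full prior range). A
  boundary flag is raised when the density at a prior edge exceeds 1% of
  its maximum — such intervals depend on the prior bound and are reported
  as open-ended in practice.
* **Budgets:** the default table size is 10⁴ draws (desk scale; the
  examples use less, serious replication uses ≥ 10⁶). All randomness flows
  from one root seed through named SeedSequence spawns: per-row simulation
  substreams make tables reproducible row by row and extendable in
  batches.

## Validation layer

* **Posterior predictive tests:** parameters are resampled from the
  weighted adjusted posterior, datasets simulated, and each statistic
  receives the doubled one-sided empirical tail probability
  `min(1, 2·min(P(sim ≤ obs), P(sim ≥ obs)))` — the simplest defensible
  two-tailed definition, fixed and documented. p-values for observations
  drawn from the predictive itself are approximately uniform (verified on
  a continuous statistic).
* **POD calibration:** truths are drawn from the prior (a grid mode exists
  for targeted bias studies, e.g. of split-time overestimation at small
  true T), a study-design dataset is simulated per truth, the full
  pipeline runs, and per-parameter 90% HPD coverage, signed mode bias and
  RMSE are aggregated; per-POD failures are logged and excluded with a
  count. Two budgets exist: a fresh reference table per POD, and the
  default *shared-table leave-one-out* mode — one prior-predictive table
  supplies both the PODs (held-out rows) and the reference simulations —
  the standard cross-validation device of ABC toolkits, which keeps the
  statistics of coverage intact at a fraction of the cost. At the
  reference configuration (100 PODs, 10⁴-row shared table, 1% retention)
  the adjusted posteriors' 90% HPD coverage for theta_A and s falls within
  the binomial(100, 0.9) 99% band.
* **Informativeness:** `sust_r2` reports the OLS R² of each (transformed)
  parameter on all standardized statistics over the table — the fraction
  of prior parameter variance the statistics can explain at all. Low R²
  (typical for the migration rates and N1 here) predicts a posterior close
  to the prior; R² is invariant to affine rescaling of statistics.

## Synthetic data

`paper_like_design()` reproduces the study layout: 10 unlinked 2 kb loci
(~20 kb), 22 + 20 chromosomes (11 + 10 diploid individuals), 25-year
generations, 1.47e-6/locus/year. The `"table1-like"` truth preset uses
the reported point estimates where the posteriors were informative
(N_A = 5475, s = 0.96, t = 193 years, N2 = 681), a mid-prior N1 (17 000)
where they were not, and no migration (analyses with and without migration
were concordant). Every dataset is bit-exactly regenerable from its
(parameters, design, seed) truth record.

What the generator emulates: the sampling design, the infinite-sites
mutation process at the pooled geometric-mean rate, and the
founder-event/recent-split regime (population 2's variation a near-subset
of population 1's, few private-2 sites). What it does not: per-locus
mutation-rate heterogeneity (all loci share the geometric mean — partly
why the preset's expected total of ~34 segregating sites sits below an
observed 52 from rate-heterogeneous loci), sequencing or phasing error,
missing data, and any selection. Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness to
those real-data complications.

## Known limitations

* The recombination scheme's independent-trees approximation ignores
  genealogical correlation along the locus; it should not be used to
  *estimate* recombination rates, only to absorb their nuisance effect.
* Local-linear adjustment with small retained samples remains slightly
  anti-conservative for weakly identified parameters even with the
  14-statistic set; rejection-only posteriors (adjust=False) are the
  conservative alternative.
* The exhaustive filter mode is exponential in the smaller matrix
  dimension and intended for ≤ ~12 × 12; beyond that the greedy mode's
  ≥ 90% calibration applies to matrices of that scale, not arbitrarily
  large ones.
* Genotype-table round-trips are exact for major-allele-coded matrices;
  other codings survive up to per-column 0/1 relabeling (irrelevant to all
  shipped statistics).
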