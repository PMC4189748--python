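# imabc

Coalescent simulation and Approximate Bayesian Computation (ABC) for the
two-population **Isolation-with-Migration (IM)** model, built for small
multilocus resequencing studies: a handful of unlinked non-coding loci
sequenced in a few dozen chromosomes from two populations, from which one
wants the demographic history — when did the populations split, how large
were they, how much of the ancestral population founded each, and how much
gene flow followed.

The motivating setting is the inference of the divergence between an
Andean highland population and a small neighbouring rainforest (Amazon
Yunga) population from ~20 kb of sequence, where the second population's
variation is essentially a subset of the first's: a recent split with a
strong founder event.

## The model

An ancestral population of effective size *N<sub>A</sub>* splits *t*
generations ago into population 1 (founding size *sN<sub>A</sub>*) and
population 2 (founding size *(1−s)N<sub>A</sub>*), *s* ∈ [0,1]. Each
descendant changes size exponentially to its present size
(*N<sub>1</sub>*, *N<sub>2</sub>*), and lineages migrate between them at
per-generation rates *m<sub>1</sub>*, *m<sub>2</sub>*. Mutation follows
the infinite-sites model. Inference works on the mutation scale —
θ = 4N<sub>e</sub>μ per locus, *T = tμ*, *M<sub>i</sub> = m<sub>i</sub>/μ*
— with the multilocus μ the geometric mean of the per-locus rates
(default 1.47 × 10⁻⁶/locus/year, 25 years per generation, hence
3.68 × 10⁻⁵ per generation).

The ABC recipe is the classic one: draw parameters from uniform priors
(θ<sub>i</sub> ∈ (0,5), T ∈ (0,0.05), M<sub>i</sub> ∈ (0,10), s ∈ (0,1)),
simulate a dataset per draw, reduce it to summary statistics (per-population
segregating sites, nucleotide diversity, haplotype counts, Tajima's D,
site-sharing counts, Hudson's F<sub>ST</sub>), keep the 1% of draws whose
standardized statistics lie closest to the observed ones, sharpen them with
Epanechnikov-weighted local-linear regression, and report weighted-KDE
posterior modes with 90% HPD intervals.

Around the inference core the package provides:

* `imabc.simulate` — an exact backward-in-time structured-coalescent
  simulator for the IM model (closed-form waiting times through the
  exponential-growth phases, optional multi-tree intra-locus recombination),
  cross-checked against msprime in the test suite;
* `imabc.recomb_filter` — four-gamete recombination filtering: exhaustive
  extraction of the largest violation-free data subset for small matrices,
  a calibrated greedy mode beyond, and a segment-split helper;
* `imabc.sustats` / `imabc.data_model` — summary statistics, FASTA and
  genotype-table IO, site-sharing classification;
* `imabc.scaling` — conversions between mutation-scaled and demographic
  units;
* `imabc.validate` — posterior predictive tests, pseudo-observed-dataset
  (POD) coverage/bias calibration, and per-parameter R² of the statistics;
* `imabc.synthetic` — study-like synthetic datasets with recorded ground
  truth (the `"table1-like"` preset places the truth at a recent split with
  a strong founder event for population 2).

## Worked example

`examples/04_abc_inference.py` generates a synthetic "observed" study at a
known truth (N<sub>A</sub> = 5475, N<sub>2</sub> = 681, s = 0.96,
t = 193 years) and runs the full pipeline at a small 5000-simulation
budget:

```
param        truth     mode               90% HPD  flag
theta_A     0.8048   0.7339   [  0.5675,   1.0274]
theta1      2.4990   2.0450   [  0.5969,   4.7750]  boundary
theta2      0.1001   3.0920   [  1.1644,   5.0000]  boundary
T           0.0003   0.0000   [  0.0000,   0.0380]  boundary
M1          0.0000   2.0548   [  0.0000,   9.2172]  boundary
M2          0.0000   0.0000   [  0.0000,   7.5147]  boundary
s           0.9600   1.0000   [  0.4462,   1.0000]  boundary

split time: mode ~0 years, 90% HPD upper bound ~25826 years (truth 193)
ancestral size: mode ~4992 individuals (truth 5475)
```

θ<sub>A</sub> is recovered well and the split-time posterior concentrates
at very recent times with a wide upper bound — exactly the behaviour such
small designs produce. The `boundary` flag marks parameters whose density
has not vanished at a prior edge (their HPD then depends on the prior), the
typical outcome for the weakly identified sizes and migration rates. The
other examples cover simulation (`01`), four-gamete filtering (`02`),
summary statistics and table IO (`03`) and the validation layer (`05`).

## Scope

The package does not implement the genealogy-sampling MCMC of the IM
program, mutation-rate estimation from interspecies divergence, VCF
ingestion, ancestral-state inference, or model choice; per-locus mutation
rates are numeric inputs.
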