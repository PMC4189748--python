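"""Multilocus summary statistics for observed/simulated data comparison.

The statistic vector summarises, per population, the across-locus mean and
standard deviation of the number of segregating sites (S), nucleotide
diversity (pi, mean pairwise differences per locus), the number of
distinct haplotypes (K) and Tajima's D; the pooled-sample mean/SD of S;
the numbers of shared, private and fixed segregating sites summed over
loci; and mean pairwise Hudson Fst across loci.  All entries are
fold-invariant (no ancestral polarisation required).

Statistics that are undefined for a locus (Tajima's D with S = 0, Fst
with zero between-population diversity) are excluded from that entry's
mean/SD rather than zero-imputed; exclusion counts are recorded.
"""

from __future__ import annotations

import math

import numpy as np

from .data_model import (POP1, POP2, MultilocusDataset, SiteMatrix,
                         shared_private_fixed_counts)

__all__ = [
    "nucleotide_diversity",
    "tajimas_d",
    "hudson_fst",
    "n_haplotypes",
    "compute_sustats",
    "SUST_NAMES",
    "DEFAULT_ABC_STATS",
]

SUST_NAMES = tuple(
    [f"{stat}_{pop}" for pop in ("pop1", "pop2") for stat in
     ("mean_S", "sd_S", "mean_pi", "sd_pi", "mean_K", "sd_K", "mean_D", "sd_D")]
    + ["mean_S_pooled", "sd_S_pooled", "shared", "private1", "private2", "fixed",
       "mean_fst"]
)

# The 14-component subset used for the ABC distance by default: across-locus
# means per population, pooled mean S, the four site-sharing counts and mean
# Fst.  The across-locus SDs are computed and available but excluded from the
# default distance: with ~100 retained draws the extra dimensions destabilise
# the local-linear adjustment more than they inform it.
DEFAULT_ABC_STATS = tuple(
    [f"mean_{stat}_{pop}" for pop in ("pop1", "pop2") for stat in ("S", "pi", "K", "D")]
    + ["mean_S_pooled", "shared", "private1", "private2", "fixed", "mean_fst"]
)


def _pop_columns(m: SiteMatrix, pop: int | None) -> np.ndarray:
    if pop is None:
        return m.alleles
    rows = m.rows_for_pop(pop)
    if len(rows) < 2:
        raise ValueError(f"population {pop} has fewer than 2 haplotypes")
    return m.alleles[rows]


def segregating_sites(m: SiteMatrix, pop: int | None = None) -> int:
    """Number of sites segregating within the (sub)sample."""
    a = _pop_columns(m, pop)
    if a.shape[1] == 0:
        return 0
    c = a.sum(axis=0)
    return int(np.count_nonzero((c > 0) & (c < a.shape[0])))


def nucleotide_diversity(m: SiteMatrix, pop: int | None = None) -> float:
    """Mean pairwise differences per locus (pi).

    Computed from allele counts: pi = sum_sites x*(n-x) / C(n,2) where x is
    the count of one allele among the n haplotypes of the (sub)sample.
    """
    a = _pop_columns(m, pop)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    if a.shape[1] == 0:
        return 0.0
    x = a.sum(axis=0, dtype=np.int64)
    return float(np.sum(x * (n - x)) / (n * (n - 1) / 2))


def n_haplotypes(m: SiteMatrix, pop: int | None = None) -> int:
    """Number of distinct haplotype strings in the (sub)sample."""
    a = _pop_columns(m, pop)
    if a.shape[1] == 0:
        return 1
    return len({row.tobytes() for row in np.ascontiguousarray(a)})


def tajimas_d(m: SiteMatrix, pop: int | None = None) -> float:
    """Tajima's D; NaN when undefined (S = 0 or n < 4)."""
    a = _pop_columns(m, pop)
    n = a.shape[0]
    s = segregating_sites(m, pop)
    if s == 0 or n < 4:
        return math.nan
    pi = nucleotide_diversity(m, pop)
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi - s / a1) / math.sqrt(var)


def hudson_fst(m: SiteMatrix) -> float:
    """Hudson's Fst: 1 - Hw/Hb with Hw the average of the two
    within-population mean pairwise differences and Hb the mean
    between-population pairwise difference.  NaN when Hb = 0."""
    r1, r2 = m.rows_for_pop(POP1), m.rows_for_pop(POP2)
    if len(r1) < 2 or len(r2) < 2:
        raise ValueError("need >= 2 haplotypes in each population")
    if m.n_sites == 0:
        return math.nan
    a1, a2 = m.alleles[r1], m.alleles[r2]
    n1, n2 = len(r1), len(r2)
    x1 = a1.sum(axis=0, dtype=np.int64)
    x2 = a2.sum(axis=0, dtype=np.int64)
    hw1 = np.sum(x1 * (n1 - x1)) / (n1 * (n1 - 1) / 2)
    hw2 = np.sum(x2 * (n2 - x2)) / (n2 * (n2 - 1) / 2)
    hb = float(np.sum(x1 * (n2 - x2) + x2 * (n1 - x1)) / (n1 * n2))
    if hb == 0.0:
        return math.nan
    return 1.0 - 0.5 * (hw1 + hw2) / hb


def _mean_sd(values) -> tuple:
    """Across-locus mean/SD excluding NaN; SD is NaN with < 2 defined loci.
    Returns (mean, sd, n_excluded)."""
    v = np.asarray(values, dtype=float)
    defined = v[~np.isnan(v)]
    excl = int(v.size - defined.size)
    if defined.size == 0:
        return math.nan, math.nan, excl
    mean = float(defined.mean())
    sd = float(defined.std(ddof=1)) if defined.size > 1 else math.nan
    return mean, sd, excl


def compute_sustats(dataset: MultilocusDataset, on_all_undefined: str = "raise") -> dict:
    """Compute the named summary-statistic vector for a dataset.

    Returns a dict keyed by :data:`SUST_NAMES` (insertion-ordered), with an
    extra ``"_exclusions"`` entry mapping statistic name to the number of
    loci excluded as undefined.  With ``on_all_undefined="raise"`` a
    statistic undefined at every locus is an error; ``"nan"`` leaves it NaN
    (the ABC engine then treats the row/entry as unusable).
    """
    per_locus: dict[str, list] = {
        f"{stat}_{pop}": [] for pop in ("pop1", "pop2")
        for stat in ("S", "pi", "K", "D")
    }
    per_locus["S_pooled"] = []
    per_locus["fst"] = []
    for m in dataset.loci:
        for pop, tag in ((POP1, "pop1"), (POP2, "pop2")):
            per_locus[f"S_{tag}"].append(segregating_sites(m, pop))
            per_locus[f"pi_{tag}"].append(nucleotide_diversity(m, pop))
            per_locus[f"K_{tag}"].append(n_haplotypes(m, pop))
            per_locus[f"D_{tag}"].append(tajimas_d(m, pop))
        per_locus["S_pooled"].append(m.n_sites)
        per_locus["fst"].append(hudson_fst(m))

    out: dict[str, float] = {}
    exclusions: dict[str, int] = {}
    for pop in ("pop1", "pop2"):
        for stat in ("S", "pi", "K", "D"):
            mean, sd, excl = _mean_sd(per_locus[f"{stat}_{pop}"])
            out[f"mean_{stat}_{pop}"] = mean
            out[f"sd_{stat}_{pop}"] = sd
            if excl:
                exclusions[f"{stat}_{pop}"] = excl
    mean, sd, excl = _mean_sd(per_locus["S_pooled"])
    out["mean_S_pooled"], out["sd_S_pooled"] = mean, sd
    counts = shared_private_fixed_counts(dataset)
    out["shared"] = float(counts["shared"])
    out["private1"] = float(counts["private1"])
    out["private2"] = float(counts["private2"])
    out["fixed"] = float(counts["fixed"])
    mean, sd, excl = _mean_sd(per_locus["fst"])
    out["mean_fst"] = mean
    if excl:
        exclusions["fst"] = excl

    if on_all_undefined == "raise":
        for name in ("mean_D_pop1", "mean_D_pop2", "mean_fst"):
            if math.isnan(out[name]):
                raise ValueError(f"statistic {name} is undefined at every locus")
    elif on_all_undefined != "nan":
        raise ValueError("on_all_undefined must be 'raise' or 'nan'")
    out["_exclusions"] = exclusions
    return out
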