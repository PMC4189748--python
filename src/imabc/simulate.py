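"""Backward-in-time coalescent simulator for the two-population
Isolation-with-Migration (IM) model.

Model: an ancestral population of constant effective size ``N_A`` splits
``t`` generations ago into population 1 (founding size ``s*N_A``) and
population 2 (founding size ``(1-s)*N_A``).  Each descendant population
changes size exponentially from its founding size to its present size
(``N1``, ``N2``).  While both descendant populations exist, lineages
migrate between them; ``m1`` is the backward-in-time per-generation
probability that a lineage currently in population 1 traces its ancestry
to population 2 (and symmetrically for ``m2``).  This matches the usual
backward convention of structured-coalescent software; note that a
*backward* move from 1 to 2 corresponds to *forward* migration of
individuals from population 2 into population 1.

Mutation follows the infinite-sites model on a finite locus: the number of
mutations is Poisson in total branch length times the whole-locus
per-generation rate, positions are drawn uniformly on the locus and
discretised to integer coordinates, and a discrete collision triggers a
redraw so every segregating site records exactly one mutation.

Waiting times are exact: the time-inhomogeneous coalescent rate during the
exponential-growth phase is inverted in closed form, so there is no
generation stepping or time discretisation anywhere.

Optional intra-locus recombination uses an independent-trees multi-segment
approximation: breakpoints arrive along the locus as a Poisson process
with intensity ``rho_per_locus`` times the current tree length, and each
segment receives a freshly simulated genealogy.  Adjacent trees are
therefore uncorrelated rather than SMC-correlated; the
``recombination_scheme`` attribute of simulated matrices records this.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .data_model import POP1, POP2, MultilocusDataset, SiteMatrix, StudyDesign

__all__ = [
    "IMParams",
    "ScaledIMParams",
    "size_trajectory",
    "simulate_locus",
    "simulate_dataset",
]

_INF = math.inf


@dataclasses.dataclass(frozen=True)
class IMParams:
    """IM-model parameters in demographic units (individuals, years).

    ``rho_per_locus`` is the whole-locus recombination rate per generation
    (0 disables recombination).
    """

    N_A: float
    N1: float
    N2: float
    s: float
    t_years: float
    m1: float = 0.0
    m2: float = 0.0
    rho_per_locus: float = 0.0

    def __post_init__(self):
        if min(self.N_A, self.N1, self.N2) <= 0:
            raise ValueError("effective sizes must be positive")
        if not 0.0 < self.s < 1.0:
            raise ValueError("s must lie strictly between 0 and 1")
        if self.t_years < 0:
            raise ValueError("t_years must be non-negative")
        if self.m1 < 0 or self.m2 < 0 or self.rho_per_locus < 0:
            raise ValueError("rates must be non-negative")
        for f in dataclasses.fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise ValueError(f"{f.name} must be finite")


@dataclasses.dataclass(frozen=True)
class ScaledIMParams:
    """IM-model parameters on the mutation scale (theta = 4*Ne*mu per
    locus, T = t*mu per year, M_i = m_i/mu per generation)."""

    theta_A: float
    theta1: float
    theta2: float
    T: float
    M1: float
    M2: float
    s: float
    rho_per_locus: float = 0.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and non-negative")
        if not 0.0 < self.s < 1.0:
            raise ValueError("s must lie strictly between 0 and 1")


def _growth_rate(n_current: float, n_founding: float, t_gen: float) -> float:
    """Backward exponential rate beta with N(tau) = N_current * exp(beta*tau)."""
    if t_gen <= 0:
        return 0.0
    return math.log(n_founding / n_current) / t_gen


def size_trajectory(params: IMParams, pop: int, tau_gen: float,
                    generation_time: float = 25.0) -> float:
    """Effective size of a descendant population ``tau_gen`` generations ago.

    Exponential interpolation between the present size (tau=0) and the
    founding size at the split; ``tau_gen`` past the split is an error
    (the ancestral regime is constant at N_A and handled separately).
    """
    t_gen = params.t_years / generation_time
    if tau_gen < 0 or tau_gen > t_gen:
        raise ValueError(f"tau_gen must lie in [0, {t_gen}]")
    if pop == POP1:
        n_cur, n_found = params.N1, params.s * params.N_A
    elif pop == POP2:
        n_cur, n_found = params.N2, (1.0 - params.s) * params.N_A
    else:
        raise ValueError("pop must be 1 or 2")
    if t_gen == 0:
        return n_cur
    beta = _growth_rate(n_cur, n_found, t_gen)
    return n_cur * math.exp(beta * tau_gen)


def _coal_wait(k: int, n_cur: float, beta: float, tau0: float, e: float) -> float:
    """Waiting time to the next coalescence among k lineages in a population
    of backward size N(tau) = n_cur * exp(beta * tau), starting at tau0.

    Solves the cumulative-hazard equation in closed form; returns inf when
    the (decaying) hazard never accumulates e before infinity.
    """
    if k < 2:
        return _INF
    a = k * (k - 1) / (4.0 * n_cur)
    if beta == 0.0:
        return e / a
    g = math.exp(-beta * tau0) - beta * e / a
    if g <= 0.0:
        return _INF
    return -math.log(g) / beta - tau0


def _simulate_genealogy(n1: int, n2: int, t_gen: float, params: IMParams, rng):
    """One genealogy: returns a list of (leaf bitmask, branch length in
    generations).  Leaves 0..n1-1 are population-1 haplotypes, the rest
    population 2."""
    masks = [[1 << i for i in range(n1)], [1 << (n1 + i) for i in range(n2)]]
    births = [[0.0] * n1, [0.0] * n2]
    branches = []

    def coalesce(pop_masks, pop_births, tau):
        k = len(pop_masks)
        i = int(rng.random() * k)
        j = int(rng.random() * (k - 1))
        if j >= i:
            j += 1
        for idx in sorted((i, j), reverse=True):
            branches.append((pop_masks[idx], tau - pop_births[idx]))
        mi, mj = pop_masks[i], pop_masks[j]
        for idx in sorted((i, j), reverse=True):
            del pop_masks[idx]
            del pop_births[idx]
        pop_masks.append(mi | mj)
        pop_births.append(tau)

    tau = 0.0
    if t_gen > 0.0:
        beta1 = _growth_rate(params.N1, params.s * params.N_A, t_gen)
        beta2 = _growth_rate(params.N2, (1.0 - params.s) * params.N_A, t_gen)
        while len(masks[0]) + len(masks[1]) > 1:
            k1, k2 = len(masks[0]), len(masks[1])
            w_c1 = _coal_wait(k1, params.N1, beta1, tau, rng.exponential())
            w_c2 = _coal_wait(k2, params.N2, beta2, tau, rng.exponential())
            w_m1 = rng.exponential() / (k1 * params.m1) if k1 and params.m1 > 0 else _INF
            w_m2 = rng.exponential() / (k2 * params.m2) if k2 and params.m2 > 0 else _INF
            w = min(w_c1, w_c2, w_m1, w_m2)
            if tau + w >= t_gen:
                tau = t_gen
                break
            tau += w
            if w == w_c1:
                coalesce(masks[0], births[0], tau)
            elif w == w_c2:
                coalesce(masks[1], births[1], tau)
            elif w == w_m1:
                i = int(rng.random() * k1)
                masks[1].append(masks[0].pop(i))
                births[1].append(births[0].pop(i))
            else:
                i = int(rng.random() * k2)
                masks[0].append(masks[1].pop(i))
                births[0].append(births[1].pop(i))

    # ancestral population: constant size N_A
    anc_masks = masks[0] + masks[1]
    anc_births = births[0] + births[1]
    while len(anc_masks) > 1:
        k = len(anc_masks)
        tau += rng.exponential() * 4.0 * params.N_A / (k * (k - 1))
        coalesce(anc_masks, anc_births, tau)
    return branches


def _drop_mutations(branches, mu_gen: float, locus_length: int, rng,
                    seg_lo: float = 0.0, seg_hi: float = 1.0, used_positions=None):
    """Poisson mutations on a genealogy; returns (positions, masks) with
    unique integer positions inside the (seg_lo, seg_hi] locus fraction."""
    if not branches:
        return [], []
    lengths = np.array([b[1] for b in branches])
    total = float(lengths.sum())
    frac = seg_hi - seg_lo
    n_mut = rng.poisson(total * mu_gen * frac)
    if n_mut == 0:
        return [], []
    cum = np.cumsum(lengths)
    used = used_positions if used_positions is not None else set()
    positions, masks = [], []
    for _ in range(n_mut):
        b = int(np.searchsorted(cum, rng.random() * total, side="right"))
        b = min(b, len(branches) - 1)
        for _attempt in range(10000):
            u = seg_lo + rng.random() * frac
            pos = int(u * locus_length) + 1
            if pos <= locus_length and pos not in used:
                break
        else:  # locus saturated: infinite-sites cannot hold; refuse silently
            continue
        used.add(pos)
        positions.append(pos)
        masks.append(branches[b][0])
    return positions, masks


def _masks_to_matrix(positions, masks, n_hap):
    order = np.argsort(positions)
    pos = np.asarray(positions, dtype=np.int64)[order]
    cols = np.zeros((n_hap, len(positions)), dtype=np.int8)
    for out_j, j in enumerate(order):
        mask = masks[j]
        for r in range(n_hap):
            if (mask >> r) & 1:
                cols[r, out_j] = 1
    return pos, cols


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_locus(params: IMParams, design: StudyDesign, locus_index: int,
                   seed) -> SiteMatrix:
    """Simulate one locus under the IM model.

    ``seed`` may be an int, a SeedSequence, or a Generator.  Haplotype rows
    are ordered population 1 first; alleles are derived-coded (0 =
    ancestral state of the mutation).
    """
    rng = _as_rng(seed)
    n1, n2 = design.n_chrom_pop1, design.n_chrom_pop2
    t_gen = params.t_years / design.generation_time
    mu_gen = design.mu_per_locus[locus_index] * design.generation_time
    L = design.locus_lengths[locus_index]
    scale = design.inheritance_scalar

    eff = params
    if scale != 1.0:
        eff = dataclasses.replace(params, N_A=params.N_A * scale,
                                  N1=params.N1 * scale, N2=params.N2 * scale)

    positions: list = []
    masks: list = []
    used: set = set()
    if params.rho_per_locus > 0.0:
        x = 0.0
        while x < 1.0:
            branches = _simulate_genealogy(n1, n2, t_gen, eff, rng)
            tree_len = sum(b[1] for b in branches)
            if tree_len > 0:
                step = rng.exponential() / (params.rho_per_locus * tree_len)
            else:
                step = 1.0
            seg_hi = min(1.0, x + step)
            p, m = _drop_mutations(branches, mu_gen, L, rng, x, seg_hi, used)
            positions += p
            masks += m
            x = seg_hi
        scheme = "independent-trees"
    else:
        branches = _simulate_genealogy(n1, n2, t_gen, eff, rng)
        p, m = _drop_mutations(branches, mu_gen, L, rng, used_positions=used)
        positions += p
        masks += m
        scheme = "single-tree"

    pos, cols = _masks_to_matrix(positions, masks, n1 + n2)
    labels = np.array([POP1] * n1 + [POP2] * n2, dtype=np.int8)
    sm = SiteMatrix(f"locus{locus_index + 1}", cols, pos, labels, L)
    sm.recombination_scheme = scheme
    return sm


def simulate_dataset(params: IMParams, design: StudyDesign, seed) -> MultilocusDataset:
    """Simulate all loci of a design; loci are independent, each drawing
    from its own substream spawned from the root seed, so the result is
    reproducible and loci can be regenerated individually."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(design.n_loci)
    loci = [
        simulate_locus(params, design, i, np.random.default_rng(children[i]))
        for i in range(design.n_loci)
    ]
    return MultilocusDataset(design, loci)
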