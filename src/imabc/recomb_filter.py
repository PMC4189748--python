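"""Four-gamete recombination filtering of haplotype matrices.

Under the infinite-sites assumption, a pair of segregating sites at which
all four haplotypes {00, 01, 10, 11} occur cannot descend from a single
non-recombining genealogy.  Analyses that assume no intra-locus
recombination therefore first extract the largest subset of the data (by
removing haplotype rows and/or sites) that contains no such four-gamete
violation.

Two search modes are provided.  For small matrices an exhaustive search
finds the row/site subset maximising the retained data quantity (kept
rows x kept sites).  Beyond that size a deterministic greedy heuristic
iteratively removes the row or site with the highest violation
participation per unit cost; by default the cost of a removal is the
number of data cells it discards, which automatically favours keeping
sequences over sites when the matrix is wider than it is tall.

A segment-split helper partitions a locus at the internal boundary that
best separates incompatibilities and keeps the larger clean side, for the
common case where recombination is concentrated in one part of a locus.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

from .data_model import SiteMatrix

__all__ = [
    "four_gamete_violations",
    "filter_recombination",
    "segment_split",
    "exhaustive_best_subset",
    "IncompatibilityReport",
]

EXACT_MAX_ROWS = 12
EXACT_MAX_SITES = 12


@dataclasses.dataclass
class IncompatibilityReport:
    """Record of a filtering pass.

    ``violating_pairs`` are the 0-based site-index pairs of the input;
    ``removed_rows``/``removed_sites`` identify the removals (haplotype ids
    and 0-based site indices); ``removed_segment`` is a (start, end)
    position range when segment splitting was used; ``dropped_monomorphic``
    lists positions that lost their polymorphism through row removal and
    were dropped from the returned matrix.
    """

    locus_id: str
    violating_pairs: list
    removed_rows: list
    removed_sites: list
    removed_segment: tuple | None = None
    dropped_monomorphic: list = dataclasses.field(default_factory=list)
    method: str = "greedy"
    retained_cells: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _column_masks(alleles: np.ndarray) -> list:
    """Each column as a bitmask of the rows carrying allele 1."""
    n, s = alleles.shape
    masks = []
    for j in range(s):
        m = 0
        col = alleles[:, j]
        for r in range(n):
            if col[r]:
                m |= 1 << r
        masks.append(m)
    return masks


def _pair_violates(ma: int, mb: int, full: int) -> bool:
    return bool(ma & mb) and bool(ma & ~mb & full) and bool(mb & ~ma & full) \
        and bool(full & ~ma & ~mb)


def four_gamete_violations(m: SiteMatrix) -> list:
    """All site-index pairs (i, j), i < j, showing all four gametes."""
    masks = _column_masks(m.alleles)
    full = (1 << m.n_haplotypes) - 1
    return [
        (i, j)
        for i in range(len(masks))
        for j in range(i + 1, len(masks))
        if _pair_violates(masks[i], masks[j], full)
    ]


def _violating_pairs_subset(masks, full: int, sites: Iterable[int]) -> list:
    sites = list(sites)
    return [
        (a, b)
        for ii, a in enumerate(sites)
        for b in sites[ii + 1:]
        if _pair_violates(masks[a] & full, masks[b] & full, full)
    ]


def _max_independent_sites(adj: list, cand: int) -> int:
    """Size of the maximum independent set in the site-conflict graph
    restricted to the candidate bitmask (branch and bound, graphs <= 12
    vertices)."""
    if cand == 0:
        return 0
    # pick the candidate vertex with the largest degree inside cand
    best_v, best_deg = -1, -1
    c = cand
    while c:
        v = (c & -c).bit_length() - 1
        c &= c - 1
        deg = bin(adj[v] & cand).count("1")
        if deg > best_deg:
            best_v, best_deg = v, deg
    if best_deg == 0:
        return bin(cand).count("1")
    with_v = 1 + _max_independent_sites(adj, cand & ~adj[best_v] & ~(1 << best_v))
    without_v = _max_independent_sites(adj, cand & ~(1 << best_v))
    return max(with_v, without_v)


def _max_independent_sites_set(adj: list, cand: int) -> int:
    """As above but returning the set (bitmask) itself."""
    if cand == 0:
        return 0
    best_v, best_deg = -1, -1
    c = cand
    while c:
        v = (c & -c).bit_length() - 1
        c &= c - 1
        deg = bin(adj[v] & cand).count("1")
        if deg > best_deg:
            best_v, best_deg = v, deg
    if best_deg == 0:
        return cand
    with_v = (1 << best_v) | _max_independent_sites_set(
        adj, cand & ~adj[best_v] & ~(1 << best_v))
    without_v = _max_independent_sites_set(adj, cand & ~(1 << best_v))
    if bin(with_v).count("1") >= bin(without_v).count("1"):
        return with_v
    return without_v


def exhaustive_best_subset(alleles: np.ndarray, mode: str = "mixed"):
    """Exhaustively find the row/site subset with the most retained cells
    and no four-gamete violation.

    Returns (row_indices, site_indices).  Only intended for matrices up to
    ~12 x 12; complexity is exponential in the smaller dimension.
    """
    n, s = alleles.shape
    masks = _column_masks(alleles)
    all_sites = (1 << s) - 1

    def sites_for_rows(row_mask: int) -> int:
        adj = [0] * s
        for i in range(s):
            for j in range(i + 1, s):
                if _pair_violates(masks[i] & row_mask, masks[j] & row_mask, row_mask):
                    adj[i] |= 1 << j
                    adj[j] |= 1 << i
        if not any(adj):
            return all_sites
        return _max_independent_sites_set(adj, all_sites)

    if mode == "sites":
        row_subsets = [(1 << n) - 1]
    elif mode == "rows":
        row_subsets = list(range(1, 1 << n))
    elif mode == "mixed":
        row_subsets = list(range(1, 1 << n))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # try large row subsets first so the cell-count bound prunes hard
    row_subsets.sort(key=lambda rm: -bin(rm).count("1"))
    best_cells, best = -1, None
    for rm in row_subsets:
        k = bin(rm).count("1")
        if k * s <= best_cells:
            break  # sorted by k: nothing better possible
        if mode == "rows":
            if _violating_pairs_subset(masks, rm, range(s)):
                continue
            site_mask = all_sites
        else:
            site_mask = sites_for_rows(rm)
        cells = k * bin(site_mask).count("1")
        if cells > best_cells:
            best_cells = cells
            best = (rm, site_mask)
    rm, sm = best
    rows = [r for r in range(n) if (rm >> r) & 1]
    sites = [j for j in range(s) if (sm >> j) & 1]
    return rows, sites


def _greedy_subset(alleles: np.ndarray, mode: str, weights: tuple):
    """Deterministic greedy removal; returns (row_indices, site_indices).

    Score of a site = number of active violating pairs containing it; score
    of a row = number of active violating pairs in which the row carries a
    minority (minimum-count) gamete class.  The candidate with the highest
    score / cost is removed; cost = cells lost x configured weight.  Ties
    prefer rows, then the lowest index.
    """
    w_row, w_site = weights
    n, s = alleles.shape
    rows = list(range(n))
    sites = list(range(s))
    while True:
        if len(rows) < 1 or len(sites) < 2:
            break
        sub = alleles[np.ix_(rows, sites)]
        masks = _column_masks(sub)
        full = (1 << len(rows)) - 1
        pairs = [
            (i, j)
            for i in range(len(sites))
            for j in range(i + 1, len(sites))
            if _pair_violates(masks[i], masks[j], full)
        ]
        if not pairs:
            break
        candidates = []  # (score_per_cost, kind_rank, index, kind)
        if mode in ("rows", "mixed") and len(rows) > 1:
            row_score = [0] * len(rows)
            for i, j in pairs:
                ma, mb = masks[i], masks[j]
                classes = [ma & mb, ma & ~mb & full, mb & ~ma & full,
                           full & ~ma & ~mb]
                sizes = [bin(c).count("1") for c in classes]
                mn = min(sz for sz in sizes if sz > 0)
                for c, sz in zip(classes, sizes):
                    if sz == mn:
                        cc = c
                        while cc:
                            r = (cc & -cc).bit_length() - 1
                            cc &= cc - 1
                            row_score[r] += 1
            cost = w_row * len(sites)
            for r, sc in enumerate(row_score):
                if sc > 0:
                    candidates.append((sc / cost, 0, r, "row"))
        if mode in ("sites", "mixed"):
            site_score = [0] * len(sites)
            for i, j in pairs:
                site_score[i] += 1
                site_score[j] += 1
            cost = w_site * len(rows)
            for k, sc in enumerate(site_score):
                if sc > 0:
                    candidates.append((sc / cost, 1, k, "site"))
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        _, _, idx, kind = candidates[0]
        if kind == "row":
            del rows[idx]
        else:
            del sites[idx]
    return rows, sites


def filter_recombination(m: SiteMatrix, mode: str = "mixed",
                         weights: tuple = (1.0, 1.0), method: str = "auto"):
    """Remove rows/sites until no four-gamete violation remains.

    Parameters
    ----------
    m : SiteMatrix
    mode : {"rows", "sites", "mixed"}
        What the search may remove.
    weights : (row_weight, site_weight)
        Relative removal-cost multipliers for the greedy search (cost of a
        removal = weight x cells lost).
    method : {"auto", "greedy", "exact"}
        ``auto`` uses the exhaustive search up to 12 x 12 and greedy beyond.

    Returns (filtered SiteMatrix, :class:`IncompatibilityReport`).  Columns
    rendered monomorphic by row removal are dropped from the matrix but
    listed separately in the report (they are retained data, not evidence
    of recombination).
    """
    if mode not in ("rows", "sites", "mixed"):
        raise ValueError(f"unknown mode {mode!r}")
    if method not in ("auto", "greedy", "exact"):
        raise ValueError(f"unknown method {method!r}")
    pairs = four_gamete_violations(m)
    if not pairs:
        report = IncompatibilityReport(m.locus_id, [], [], [], method="none",
                                       retained_cells=m.n_haplotypes * m.n_sites)
        return m, report
    use_exact = method == "exact" or (
        method == "auto" and m.n_haplotypes <= EXACT_MAX_ROWS
        and m.n_sites <= EXACT_MAX_SITES)
    if use_exact:
        rows, sites = exhaustive_best_subset(m.alleles, mode)
        used = "exact"
    else:
        rows, sites = _greedy_subset(m.alleles, mode, weights)
        used = "greedy"
    removed_rows = [m.haplotype_ids[r] for r in range(m.n_haplotypes) if r not in set(rows)]
    removed_sites = sorted(set(range(m.n_sites)) - set(sites))
    kept = m.submatrix(rows=rows, sites=sites)
    cells = kept.n_haplotypes * kept.n_sites
    filtered = kept.drop_monomorphic()
    dropped = sorted(set(kept.positions) - set(filtered.positions))
    report = IncompatibilityReport(
        m.locus_id, pairs, removed_rows, removed_sites,
        dropped_monomorphic=[int(p) for p in dropped],
        method=used, retained_cells=int(cells),
    )
    return filtered, report


def segment_split(m: SiteMatrix):
    """Split the locus at the inter-site boundary with the fewest spanning
    violations and keep the larger side (further filtered if needed).

    Emulates the common practice of discarding one recombining half of a
    locus instead of scattered rows/sites.  Returns (SiteMatrix, report)
    with ``removed_segment`` set to the discarded position range.
    """
    pairs = four_gamete_violations(m)
    if not pairs or m.n_sites < 2:
        report = IncompatibilityReport(m.locus_id, pairs, [], [], method="none",
                                       retained_cells=m.n_haplotypes * m.n_sites)
        return m, report
    best = None
    for cut in range(1, m.n_sites):  # sites [0, cut) | [cut, n_sites)
        spanning = sum(1 for i, j in pairs if i < cut <= j)
        if best is None or spanning < best[0]:
            best = (spanning, cut)
    _, cut = best
    left_sites = list(range(cut))
    right_sites = list(range(cut, m.n_sites))
    if len(left_sites) >= len(right_sites):
        keep, drop = left_sites, right_sites
    else:
        keep, drop = right_sites, left_sites
    segment = (int(m.positions[drop[0]]), int(m.positions[drop[-1]]))
    kept = m.submatrix(sites=keep)
    filtered, inner = filter_recombination(kept)
    inner_removed = [keep[k] for k in inner.removed_sites]
    report = IncompatibilityReport(
        m.locus_id, pairs, inner.removed_rows,
        sorted(set(drop) | set(inner_removed)),
        removed_segment=segment,
        dropped_monomorphic=inner.dropped_monomorphic,
        method=f"segment+{inner.method}",
        retained_cells=inner.retained_cells,
    )
    return filtered, report
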