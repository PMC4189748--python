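"""Four-gamete detection and the exact/greedy incompatibility filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from imabc import (SiteMatrix, filter_recombination, four_gamete_violations,
                   segment_split)
from imabc.recomb_filter import exhaustive_best_subset


binary_matrices = arrays(np.int8, shape=st.tuples(st.integers(4, 10),
                                                  st.integers(2, 7)),
                         elements=st.integers(0, 1))


def matrix(cols, pops=None, positions=None):
    a = np.asarray(cols, dtype=np.int8).T  # cols given column-wise
    n = a.shape[0]
    pops = pops or [1] * n
    if positions is None:
        positions = np.arange(1, a.shape[1] + 1) * 10
    return SiteMatrix("locusR", a, positions, pops, 1000)


def brute_force_violations(alleles):
    """Oracle: literal enumeration of the gamete sets of every site pair."""
    n, s = alleles.shape
    out = []
    for i in range(s):
        for j in range(i + 1, s):
            gametes = {(int(alleles[r, i]), int(alleles[r, j])) for r in range(n)}
            if len(gametes) == 4:
                out.append((i, j))
    return out


def random_segregating(rng, n, s):
    while True:
        a = rng.integers(0, 2, size=(n, s)).astype(np.int8)
        cs = a.sum(axis=0)
        if np.all((cs > 0) & (cs < n)):
            return a


class TestFourGameteViolations:
    def test_engineered_pair(self):
        m = matrix([[1, 1, 0, 0], [1, 0, 1, 0]])
        assert four_gamete_violations(m) == [(0, 1)]

    def test_singleton_column_never_violates(self, rng):
        # a singleton column can contribute at most 3 distinct gametes
        for _ in range(20):
            a = random_segregating(rng, 8, 5)
            a[:, 0] = 0
            a[3, 0] = 1
            m = SiteMatrix("locusR", a, np.arange(1, 6), [1] * 8, 100)
            assert all(0 not in pair for pair in four_gamete_violations(m))

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(30):
            a = random_segregating(rng, 8, 6)
            m = SiteMatrix("locusR", a, np.arange(1, 7), [1] * 8, 100)
            assert four_gamete_violations(m) == brute_force_violations(a)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(binary_matrices)
    def test_matches_brute_force_property(self, a):
        m = SiteMatrix("locusH", a, np.arange(1, a.shape[1] + 1),
                       [1] * a.shape[0], 100, validate=False)
        assert four_gamete_violations(m) == brute_force_violations(a)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(binary_matrices)
    def test_filter_output_clean_for_any_binary_matrix(self, a):
        m = SiteMatrix("locusH", a, np.arange(1, a.shape[1] + 1),
                       [1] * a.shape[0], 100, validate=False)
        out, _ = filter_recombination(m, method="greedy")
        assert four_gamete_violations(out) == []


class TestFilterRecombination:
    def test_compatible_matrix_unchanged(self):
        m = matrix([[1, 1, 0, 0], [1, 1, 1, 0]])  # nested: no violation
        out, report = filter_recombination(m)
        assert out == m
        assert report.violating_pairs == []
        assert report.removed_rows == [] and report.removed_sites == []

    def test_single_violation_cheapest_removal_matches_exhaustive(self):
        # the violating pair has three singleton gamete classes: removing one
        # row (16 cells kept) beats removing one site (15 cells kept)
        cols = [
            [1, 1, 0, 0, 0],
            [1, 0, 1, 0, 0],
            [1, 1, 1, 1, 0],
            [0, 0, 0, 1, 1],
        ]
        m = matrix(cols)
        rows, sites = exhaustive_best_subset(m.alleles, "mixed")
        assert len(rows) * len(sites) == 16
        out, report = filter_recombination(m, method="exact")
        assert report.retained_cells == 16
        assert len(report.removed_rows) == 1 and report.removed_sites == []
        assert four_gamete_violations(out) == []

    def test_one_haplotype_resolving_multiple_pairs_is_removed(self):
        # r6 is the single recombinant behind both violating pairs
        rows = [
            [1, 1, 0],
            [1, 1, 0],
            [1, 0, 0],
            [0, 0, 1],
            [0, 0, 1],
            [0, 0, 0],
            [0, 1, 1],
        ]
        a = np.asarray(rows, dtype=np.int8)
        m = SiteMatrix("locusR", a, [10, 20, 30], [1] * 7, 1000)
        assert len(four_gamete_violations(m)) == 2
        for method in ("greedy", "exact"):
            out, report = filter_recombination(m, method=method)
            assert report.removed_rows == ["locusR.h6"], method
            assert report.removed_sites == []
            assert four_gamete_violations(out) == []

    def test_output_always_clean_and_idempotent(self, rng):
        for _ in range(15):
            a = random_segregating(rng, 10, 8)
            m = SiteMatrix("locusR", a, np.arange(1, 9), [1] * 10, 100)
            out, _ = filter_recombination(m, method="greedy")
            assert four_gamete_violations(out) == []
            again, report = filter_recombination(out, method="greedy")
            assert again == out
            assert report.method == "none"

    @pytest.mark.parametrize("mode", ["rows", "sites", "mixed"])
    def test_modes_produce_clean_output(self, rng, mode):
        a = random_segregating(rng, 9, 7)
        m = SiteMatrix("locusR", a, np.arange(1, 8), [1] * 9, 100)
        out, report = filter_recombination(m, mode=mode, method="greedy")
        assert four_gamete_violations(out) == []
        if mode == "rows":
            assert report.removed_sites == []
        if mode == "sites":
            assert report.removed_rows == []

    def test_unknown_mode_rejected(self):
        m = matrix([[1, 1, 0, 0], [1, 0, 1, 0]])
        with pytest.raises(ValueError, match="mode"):
            filter_recombination(m, mode="columns")

    def test_greedy_close_to_exact_on_small_matrices(self, rng):
        # calibration property at reduced trial count (the acceptance suite
        # runs the full 200-trial version)
        ratios = []
        for _ in range(30):
            a = random_segregating(rng, 9, 7)
            rows, sites = exhaustive_best_subset(a, "mixed")
            exact_cells = len(rows) * len(sites)
            m = SiteMatrix("locusR", a, np.arange(1, 8), [1] * 9, 100)
            _, report = filter_recombination(m, method="greedy")
            ratios.append(report.retained_cells / exact_cells)
        assert np.mean(ratios) >= 0.9


class TestSegmentSplit:
    def test_concentrated_incompatibility_drops_one_side(self, rng):
        # left block: clean nested columns; right block: recombinant mess
        left = np.zeros((10, 3), dtype=np.int8)
        left[:6, 0] = 1
        left[:4, 1] = 1
        left[:2, 2] = 1
        right = random_segregating(rng, 10, 2)
        right[0, 0], right[0, 1] = 1, 1
        right[1, 0], right[1, 1] = 1, 0
        right[2, 0], right[2, 1] = 0, 1
        right[3, 0], right[3, 1] = 0, 0
        a = np.hstack([left, right])
        m = SiteMatrix("locusR", a, [10, 20, 30, 800, 900], [1] * 10, 1000)
        out, report = segment_split(m)
        assert four_gamete_violations(out) == []
        assert report.removed_segment is not None
        assert out.n_sites >= 1
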