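"""Summary statistics against brute-force oracles and neutral expectations."""

import itertools
import math

import numpy as np
import pytest

from imabc import (IMParams, MultilocusDataset, SiteMatrix, StudyDesign,
                   compute_sustats, hudson_fst, n_haplotypes,
                   nucleotide_diversity, simulate_locus, tajimas_d)
from imabc.data_model import POP1


def matrix(rows, pops, L=100):
    a = np.asarray(rows, dtype=np.int8)
    return SiteMatrix("locusT", a, np.arange(1, a.shape[1] + 1), pops, L)


def brute_pairwise_mean(a):
    pairs = list(itertools.combinations(range(a.shape[0]), 2))
    return sum(int(np.sum(a[i] != a[j])) for i, j in pairs) / len(pairs)


class TestNucleotideDiversity:
    def test_identical_haplotypes(self):
        m = matrix(np.zeros((4, 0)), [1, 1, 2, 2])
        assert nucleotide_diversity(m) == 0.0

    def test_three_haplotype_example(self):
        # pairwise differences of {00, 01, 11}: 1, 2, 1 -> mean 4/3
        m = matrix([[0, 0], [0, 1], [1, 1]], [1, 1, 1])
        assert nucleotide_diversity(m) == pytest.approx(4 / 3)

    def test_matches_brute_force_and_row_permutation(self, rng):
        for _ in range(10):
            a = rng.integers(0, 2, size=(8, 6))
            a[0] = 1 - a[1]  # keep columns segregating cheaply
            m = matrix(a, [1] * 8)
            assert nucleotide_diversity(m) == pytest.approx(brute_pairwise_mean(a))
            perm = rng.permutation(8)
            assert nucleotide_diversity(matrix(a[perm], [1] * 8)) == \
                pytest.approx(nucleotide_diversity(m))


class TestTajimasD:
    def test_undefined_when_no_variation(self):
        m = matrix(np.zeros((5, 0)), [1] * 5)
        assert math.isnan(tajimas_d(m))

    def test_hand_formula_on_small_example(self, rng):
        # independent re-derivation of the standardized formula
        a = rng.integers(0, 2, size=(6, 5))
        a[0] = 1 - a[1]
        m = matrix(a, [1] * 6)
        n = 6
        s = int(np.count_nonzero((a.sum(0) > 0) & (a.sum(0) < n)))
        pi = brute_pairwise_mean(a)
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        expected = (pi - s / a1) / math.sqrt(c1 / a1 * s
                                             + c2 / (a1**2 + a2) * s * (s - 1))
        assert tajimas_d(m) == pytest.approx(expected)

    def test_neutral_mean_near_zero(self, rng):
        # constant-size neutral coalescent, n = 20: E[D] ~ 0
        d = StudyDesign(1, (2000,), (1.47e-6,), 10, 10)
        p = IMParams(N_A=2e4, N1=2e4, N2=2e4, s=0.5, t_years=0.0)
        vals = []
        for _ in range(2000):
            m = simulate_locus(p, d, 0, rng)
            v = tajimas_d(m)
            if not math.isnan(v):
                vals.append(v)
        assert abs(np.mean(vals)) < 0.1


class TestHudsonFst:
    def test_identical_populations_near_zero(self, rng):
        # both samples drawn from the same haplotype pool: E[Fst] ~ 0
        pool = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        a = pool[rng.integers(0, 4, size=120)]
        m = matrix(a, [1] * 60 + [2] * 60)
        assert hudson_fst(m) == pytest.approx(0.0, abs=0.05)

    def test_fixed_difference_gives_one(self):
        m = matrix([[0, 0]] * 3 + [[1, 1]] * 3, [1] * 3 + [2] * 3)
        assert hudson_fst(m) == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            a = rng.integers(0, 2, size=(10, 6))
            a[0] = 1 - a[1]
            pops = np.array([1] * 5 + [2] * 5)
            m = matrix(a, pops)
            a1, a2 = a[:5], a[5:]
            hw = 0.5 * (brute_pairwise_mean(a1) + brute_pairwise_mean(a2))
            hb = np.mean([[np.sum(x != y) for y in a2] for x in a1])
            if hb > 0:
                assert hudson_fst(m) == pytest.approx(1 - hw / hb)


class TestComputeSustats:
    def build_dataset(self, seed=5):
        d = StudyDesign(3, (1000,) * 3, (1.47e-6,) * 3, 8, 6)
        p = IMParams(N_A=1e4, N1=1e4, N2=1e4, s=0.5, t_years=2e4)
        loci = [simulate_locus(p, d, i, seed + i) for i in range(3)]
        return MultilocusDataset(d, loci)

    def test_counts_sum_to_total_sites(self):
        ds = self.build_dataset()
        st = compute_sustats(ds, on_all_undefined="nan")
        total = st["shared"] + st["private1"] + st["private2"] + st["fixed"]
        assert total == ds.total_segregating_sites

    def test_invariant_to_locus_and_row_order(self, rng):
        ds = self.build_dataset()
        st = compute_sustats(ds, on_all_undefined="nan")
        shuffled_loci = [ds.loci[2], ds.loci[0], ds.loci[1]]
        d2 = StudyDesign(3, tuple(m.locus_length for m in shuffled_loci),
                         ds.design.mu_per_locus, 8, 6)
        st2 = compute_sustats(MultilocusDataset(d2, shuffled_loci),
                              on_all_undefined="nan")
        perm_loci = []
        for m in ds.loci:
            order = np.concatenate([rng.permutation(8), 8 + rng.permutation(6)])
            perm_loci.append(m.submatrix(rows=order))
        st3 = compute_sustats(MultilocusDataset(ds.design, perm_loci),
                              on_all_undefined="nan")
        for k in st:
            if k.startswith("_"):
                continue
            for other in (st2, st3):
                if math.isnan(st[k]):
                    assert math.isnan(other[k])
                else:
                    assert other[k] == pytest.approx(st[k])

    def test_subset_population_has_no_private_sites(self):
        # pop2 haplotypes drawn from pop1's set -> private2 = 0
        base = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0], [1, 1, 1]], dtype=np.int8)
        a = np.vstack([base, base[:2], base[:2]])
        d = StudyDesign(1, (100,), (1.47e-6,), 4, 4)
        m = SiteMatrix("locus1", a, [1, 2, 3], [1] * 4 + [2] * 4, 100)
        st = compute_sustats(MultilocusDataset(d, [m]), on_all_undefined="nan")
        assert st["private2"] == 0

    def test_single_locus_sd_undefined(self):
        d = StudyDesign(1, (1000,), (1.47e-6,), 8, 6)
        p = IMParams(N_A=1e4, N1=1e4, N2=1e4, s=0.5, t_years=0.0)
        m = simulate_locus(p, d, 0, seed=10)
        st = compute_sustats(MultilocusDataset(d, [m]), on_all_undefined="nan")
        assert math.isnan(st["sd_S_pop1"])
        assert st["mean_S_pooled"] == m.n_sites

    def test_all_undefined_statistic_raises(self):
        d = StudyDesign(1, (1000,), (1e-30,), 8, 6)
        p = IMParams(N_A=1e4, N1=1e4, N2=1e4, s=0.5, t_years=0.0)
        m = simulate_locus(p, d, 0, seed=1)
        with pytest.raises(ValueError, match="mean_D"):
            compute_sustats(MultilocusDataset(d, [m]))

    def test_fst_nondecreasing_with_split_time(self, rng):
        d = StudyDesign(1, (2000,), (1.47e-6,), 8, 8)
        means = []
        for t in (2e3, 5e4, 1e6):
            p = IMParams(N_A=5e3, N1=5e3, N2=5e3, s=0.5, t_years=t)
            vals = []
            for _ in range(500):
                m = simulate_locus(p, d, 0, rng)
                v = hudson_fst(m) if m.n_sites else math.nan
                if not math.isnan(v):
                    vals.append(v)
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_distinct_haplotype_count(self):
        m = matrix([[0, 0], [0, 0], [0, 1], [1, 1]], [1] * 4)
        assert n_haplotypes(m, POP1) == 3
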