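"""fst: Weir-Cockerham components, window estimates, heterozygosity tracks."""

import numpy as np
import pytest

from sweepscan import fst, genotype_io
from sweepscan.types import PopulationMap
from tests.conftest import make_vt


def hm_from_genotypes(genotypes):
    """Haplotype matrix from per-individual (a, b) phased genotype tuples
    at a single site -- one column."""
    return np.array(genotypes, dtype=np.int8).reshape(-1, 1)


def independent_wc(g1, g2):
    """Independent two-population Weir & Cockerham 1984 theta-hat.

    Written from the genotype-count formulation (not the package's
    frequency algebra): sample sizes, allele frequencies and heterozygote
    proportions enter through Weir & Cockerham's own n_bar / n_c / CV^2
    quantities, so shared algebra bugs are unlikely.
    """
    g1, g2 = np.asarray(g1), np.asarray(g2)
    stats = []
    for g in (g1, g2):
        n = len(g)
        p = g.sum() / (2 * n)
        h = (g == 1).mean()
        stats.append((n, p, h))
    r = 2
    n1, p1, h1 = stats[0]
    n2, p2, h2 = stats[1]
    nbar = (n1 + n2) / r
    CV2 = ((n1 - nbar) ** 2 + (n2 - nbar) ** 2) / ((r - 1) * nbar ** 2)
    nc = nbar * (1 - CV2 / r)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar)
                                            - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWcComponents:
    def test_fixed_opposite_alleles(self):
        # two pools of 4 diploids fixed for opposite alleles, no heterozygotes
        hm_a = hm_from_genotypes([(1, 1)] * 4)
        hm_b = hm_from_genotypes([(0, 0)] * 4)
        a, b, c, usable = fst.wc_components(hm_a, hm_b)
        assert usable[0]
        assert a[0] == pytest.approx(0.5)
        assert b[0] == pytest.approx(0.0)
        assert c[0] == pytest.approx(0.0)
        assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(1.0)

    def test_identical_pools_give_nonpositive_theta(self):
        geno = [(0, 0), (0, 1), (1, 1), (0, 1)]
        hm_a = hm_from_genotypes(geno)
        hm_b = hm_from_genotypes(geno)
        t = fst.theta_site(hm_a, hm_b)
        assert t[0] <= 0.0

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            g1 = rng.integers(0, 3, size=rng.integers(3, 12))
            g2 = rng.integers(0, 3, size=rng.integers(3, 12))
            p_union = (g1.sum() + g2.sum()) / (2 * (len(g1) + len(g2)))
            if p_union in (0.0, 1.0):
                continue
            hm_a = hm_from_genotypes([(1, g - 1) if g == 2 else (0, g)
                                      for g in g1])
            hm_b = hm_from_genotypes([(1, g - 1) if g == 2 else (0, g)
                                      for g in g2])
            a, b, c, usable = fst.wc_components(hm_a, hm_b)
            ea, eb, ec = independent_wc(g1, g2)
            assert a[0] == pytest.approx(ea, abs=1e-12)
            assert b[0] == pytest.approx(eb, abs=1e-12)
            assert c[0] == pytest.approx(ec, abs=1e-12)

    def test_pool_swap_symmetry(self):
        rng = np.random.default_rng(32)
        hm_a = rng.integers(0, 2, size=(10, 8)).astype(np.int8)
        hm_b = rng.integers(0, 2, size=(16, 8)).astype(np.int8)
        a1, b1, c1, u1 = fst.wc_components(hm_a, hm_b)
        a2, b2, c2, u2 = fst.wc_components(hm_b, hm_a)
        assert a1 == pytest.approx(a2)
        assert b1 == pytest.approx(b2)
        assert c1 == pytest.approx(c2)


class TestWindowFst:
    def test_single_site_window_equals_theta(self):
        hm_a = hm_from_genotypes([(1, 1)] * 4)
        hm_b = hm_from_genotypes([(0, 0)] * 4)
        a, b, c, usable = fst.wc_components(hm_a, hm_b)
        track = fst.window_fst(a, b, c, usable, make_vt([5000]))
        assert track["value"].tolist() == [pytest.approx(1.0)]

    def test_two_site_window_is_ratio_of_sums(self):
        rng = np.random.default_rng(33)
        hm_a = rng.integers(0, 2, size=(12, 2)).astype(np.int8)
        hm_b = rng.integers(0, 2, size=(12, 2)).astype(np.int8)
        a, b, c, usable = fst.wc_components(hm_a, hm_b)
        assert usable.all()
        track = fst.window_fst(a, b, c, usable, make_vt([2000, 7000]))
        assert len(track) == 1
        assert track["value"][0] == pytest.approx(a.sum() / (a + b + c).sum())

    def test_site_order_within_window_is_irrelevant(self):
        rng = np.random.default_rng(34)
        hm_a = rng.integers(0, 2, size=(12, 4)).astype(np.int8)
        hm_b = rng.integers(0, 2, size=(12, 4)).astype(np.int8)
        a, b, c, u = fst.wc_components(hm_a, hm_b)
        vt = make_vt([1000, 2000, 3000, 4000])
        t1 = fst.window_fst(a, b, c, u, vt)
        order = [2, 0, 3, 1]
        # same window, per-site components fed in a different order
        t2 = fst.window_fst(a[order], b[order], c[order], u[order], vt)
        assert t1["value"][0] == pytest.approx(t2["value"][0])


class TestHetAndFreq:
    def _pm(self):
        return PopulationMap(
            pool_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            reference_pool="A")

    def test_all_heterozygous(self):
        pm = self._pm()
        ids = ["a1", "a2", "b1", "b2"]
        hm = np.array([[0, 0], [1, 1], [0, 1], [1, 0],
                       [0, 0], [0, 0], [0, 0], [0, 0]], dtype=np.int8)
        track = fst.window_het_and_freq(hm, make_vt([100, 200]), pm, "A", ids)
        assert track["het"][0] == pytest.approx(1.0)

    def test_fixed_pool_het_zero_major_one(self):
        pm = self._pm()
        ids = ["a1", "a2", "b1", "b2"]
        hm = np.zeros((8, 2), dtype=np.int8)
        hm[:4] = 1  # pool A fixed derived
        track = fst.window_het_and_freq(hm, make_vt([100, 200]), pm, "A", ids)
        assert track["het"][0] == pytest.approx(0.0)
        assert track["major_freq"][0] == pytest.approx(1.0)
        # pool B carries none of A's major allele
        assert track["freq_B"][0] == pytest.approx(0.0)

    def test_mixed_window_hand_counted(self):
        pm = self._pm()
        ids = ["a1", "a2", "b1", "b2"]
        # site 1: A = {0|1, 1|1} -> het 1/2, freq1 3/4 -> major derived 0.75
        # site 2: A = {0|0, 0|1} -> het 1/2, freq1 1/4 -> major ancestral 0.75
        # B is fixed derived at both sites
        hm = np.array([[0, 0], [1, 0], [1, 0], [1, 1],
                       [1, 1], [1, 1], [1, 1], [1, 1]], dtype=np.int8)
        track = fst.window_het_and_freq(hm, make_vt([100, 200]), pm, "A", ids)
        assert track["het"][0] == pytest.approx(0.5)
        assert track["major_freq"][0] == pytest.approx(0.75)
        # B frequencies of A's major allele: site1 allele1 -> 1.0; site2
        # allele0 -> 0.0; window mean 0.5
        assert track["freq_B"][0] == pytest.approx(0.5)


class TestRecoveryProperties:
    def test_neutral_fst_small_and_sweep_window_in_upper_tail(self, sweep_sim):
        vt, hm, pm, ids, truths = sweep_sim
        track = fst.fst_track(hm, vt, pm, "DOM1", ids)
        hard = next(t for t in truths if t.kind == "hard")
        w = (hard.position - 1) // 10_000
        row = track[(track["start"] == w * 10_000)]
        assert not row.empty
        q90 = track["value"].quantile(0.9)
        assert row["value"].iloc[0] >= q90
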