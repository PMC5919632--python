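"""regions: permutation thresholds, outlier calling and interval calculus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sweepscan import regions, ihs as ihs_mod
from sweepscan.regions import ThresholdSpec
from tests.conftest import make_vt


def track(values, width=10_000, chrom="1"):
    values = list(values)
    return pd.DataFrame({
        "chrom": [chrom] * len(values),
        "start": np.arange(len(values)) * width,
        "end": (np.arange(len(values)) + 1) * width,
        "n_snps": 1,
        "value": values,
    })


def spec(null, threshold=None, method="fst"):
    null = np.asarray(null, dtype=float)
    thr = float(np.quantile(null, 0.95)) if threshold is None else threshold
    return ThresholdSpec(method=method, n_permutations=1, level=0.05,
                         threshold=thr, null_values=null)


class TestThresholds:
    def test_same_seed_same_threshold(self, small_sim):
        vt, hm, pm, ids, _ = small_sim
        s1 = regions.permute_fst_null(hm, vt, pm, "DOM1", ids, n_perm=10, seed=5)
        s2 = regions.permute_fst_null(hm, vt, pm, "DOM1", ids, n_perm=10, seed=5)
        assert s1.threshold == s2.threshold
        assert np.array_equal(s1.null_values, s2.null_values)

    def test_single_permutation_degenerate(self, small_sim):
        vt, hm, pm, ids, _ = small_sim
        s = regions.permute_fst_null(hm, vt, pm, "DOM1", ids, n_perm=1, seed=2)
        assert s.threshold == pytest.approx(np.quantile(s.null_values, 0.95))

    def test_exchangeable_pools_flag_about_five_percent(self):
        # both pools drawn from one population: the label permutation is the
        # exact null, so ~5% of windows should exceed the threshold
        from sweepscan.simulate import SimConfig, simulate
        from sweepscan import fst

        cfg = SimConfig(seed=77, n_sites=2500, chrom_length=3_000_000,
                        t_burnin=120, t_split=0)
        vt, hm, pm, ids, _ = simulate(cfg)
        s = regions.permute_fst_null(hm, vt, pm, "DOM1", ids, n_perm=150, seed=3)
        obs = fst.fst_track(hm, vt, pm, "DOM1", ids)
        frac = (obs["value"].to_numpy() > s.threshold).mean()
        n = len(obs)
        se = np.sqrt(0.05 * 0.95 / n)
        assert frac <= 0.05 + 3 * se

    def test_all_equal_scores_give_no_outliers(self):
        df = pd.DataFrame({"chrom": ["1"] * 6,
                           "pos": np.arange(1, 7) * 7000,
                           "iHH_A": 1.0, "iHH_D": 1.0, "ihs": 0.7})
        s = regions.permute_ihs_null(df, n_perm=20, seed=1)
        obs = ihs_mod.window_abs_ihs(df)
        out = regions.call_outliers(obs, s)
        assert out.empty  # equal values never strictly exceed the threshold

    def test_threshold_close_to_exhaustive_permutation_quantile(self):
        # 6-site toy genome: every permutation of scores over positions can
        # be enumerated; compare the sampled null's quantile to exhaustive
        scores = np.array([0.1, 0.4, 0.9, 1.7, 2.2, 3.0])
        pos = np.array([2000, 8000, 12_000, 19_000, 23_000, 29_000])
        df = pd.DataFrame({"chrom": ["1"] * 6, "pos": pos,
                           "iHH_A": 1.0, "iHH_D": 1.0, "ihs": scores})
        exhaustive = []
        for perm in itertools.permutations(scores):
            d = df.assign(ihs=list(perm))
            exhaustive.append(ihs_mod.window_abs_ihs(d)["value"].to_numpy())
        exact = np.quantile(np.concatenate(exhaustive), 0.95)
        s = regions.permute_ihs_null(df, n_perm=400, seed=9)
        assert s.threshold == pytest.approx(exact, rel=0.05)


class TestCallOutliers:
    def test_equal_to_threshold_is_not_an_outlier(self):
        out = regions.call_outliers(track([0.5, 0.7]), spec([0.1], threshold=0.7))
        assert out.empty

    def test_empty_track(self):
        out = regions.call_outliers(track([]), spec([0.1]))
        assert out.empty

    def test_empirical_p_counting(self):
        null = np.arange(1, 101, dtype=float)
        s = spec(null, threshold=90.0)
        out = regions.call_outliers(track([96.0]), s)
        assert out["empirical_p"].tolist() == [pytest.approx(0.05)]


class TestRegionCalculus:
    def test_psr_clipped_at_chromosome_start(self):
        out = track([1.0])
        out.loc[0, ["start", "end"]] = (20_000, 30_000)
        psr = regions.build_psr(out.assign(empirical_p=0.01), "PSR_iHS")
        assert psr[["start", "end"]].values.tolist() == [[0, 125_000]]

    def test_nearby_outliers_merge(self):
        t = pd.DataFrame({"chrom": ["1", "1"], "start": [0, 150_000],
                          "end": [10_000, 160_000], "n_snps": 1,
                          "value": [1.0, 2.0], "empirical_p": [0.01, 0.02]})
        psr = regions.build_psr(t, "PSR_CLR")
        assert len(psr) == 1
        assert psr["n_windows"].tolist() == [2]
        assert psr["best_stat"].tolist() == [2.0]

    def test_no_outliers_empty_set(self):
        psr = regions.build_psr(track([]), "PSR_iHS")
        assert psr.empty

    def test_merge_ihs_clr_within_gap(self):
        a = pd.DataFrame([("1", 0, 125_000, "PSR_iHS", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        b = pd.DataFrame([("1", 200_000, 325_000, "PSR_CLR", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        merged = regions.merge_ihs_clr(a, b)
        assert merged[["start", "end"]].values.tolist() == [[0, 325_000]]

    def test_merge_ihs_clr_beyond_gap_kept_separate(self):
        a = pd.DataFrame([("1", 0, 100_000, "PSR_iHS", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        b = pd.DataFrame([("1", 300_001, 400_000, "PSR_CLR", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        merged = regions.merge_ihs_clr(a, b)
        assert len(merged) == 2

    def test_merge_with_empty_input_is_identity(self):
        a = pd.DataFrame([("1", 0, 100_000, "PSR_iHS", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        empty = regions._empty_regions("PSR_CLR")
        merged = regions.merge_ihs_clr(a, empty)
        assert merged[["chrom", "start", "end"]].values.tolist() == [["1", 0, 100_000]]

    @pytest.mark.parametrize("fst_iv,expected", [
        ((99, 200), 1),   # 1 bp overlap -> retained in full extent
        ((100, 200), 0),  # half-open touch -> dropped
    ])
    def test_intersect_boundary(self, fst_iv, expected):
        a = pd.DataFrame([("1", 0, 100, "IHS_CLR", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        f = pd.DataFrame([("1", *fst_iv, "FST", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        art = regions.intersect_artificial(a, f)
        assert len(art) == expected
        if expected:
            assert art[["start", "end"]].values.tolist() == [[0, 100]]

    def test_disjoint_chromosomes_empty(self):
        a = pd.DataFrame([("1", 0, 100, "IHS_CLR", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        f = pd.DataFrame([("2", 0, 100, "FST", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        assert regions.intersect_artificial(a, f).empty

    def test_against_brute_force_interval_oracle(self):
        """merge/intersect agree with per-bp boolean arrays on random input."""
        rng = np.random.default_rng(55)
        L = 2000
        for _ in range(25):
            def rand_regions(tag, n):
                starts = rng.integers(0, L - 50, size=n)
                ends = starts + rng.integers(1, 120, size=n)
                return pd.DataFrame({
                    "chrom": "1", "start": starts, "end": np.minimum(ends, L),
                    "tag": tag, "n_windows": 1, "best_stat": 1.0,
                    "empirical_p": 0.01})

            a = rand_regions("PSR_iHS", rng.integers(1, 6))
            gap = int(rng.integers(0, 100))
            merged = regions.merge_regions(a, gap=gap)
            cover = np.zeros(L + 200, dtype=bool)
            for r in a.itertuples(index=False):
                cover[r.start:r.end] = True
            # oracle merge: close gaps <= gap, then read off runs
            runs = []
            i = 0
            arr = cover.copy()
            idx = np.flatnonzero(arr)
            if idx.size:
                segs = [[idx[0], idx[0] + 1]]
                for x in idx[1:]:
                    if x <= segs[-1][1] - 1 + 1:
                        segs[-1][1] = x + 1
                    else:
                        segs.append([x, x + 1])
                fused = [segs[0]]
                for s0, e0 in segs[1:]:
                    if s0 - fused[-1][1] <= gap:
                        fused[-1][1] = e0
                    else:
                        fused.append([s0, e0])
                runs = fused
            assert merged[["start", "end"]].values.tolist() == runs

            # intersect oracle
            b = rand_regions("FST", rng.integers(1, 6))
            b = regions.merge_regions(b)
            art = regions.intersect_artificial(merged.assign(tag="IHS_CLR"), b)
            keep = []
            for r in merged.itertuples(index=False):
                hit = any(min(r.end, q.end) - max(r.start, q.start) > 0
                          for q in b.itertuples(index=False))
                if hit:
                    keep.append([r.start, r.end])
            assert art[["start", "end"]].values.tolist() == keep

    def test_artificial_span_within_ihs_clr_span(self, small_sim):
        a = pd.DataFrame([("1", 0, 100, "IHS_CLR", 1, 1.0, 0.01),
                          ("1", 500, 900, "IHS_CLR", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        f = pd.DataFrame([("1", 50, 60, "FST", 1, 1.0, 0.01)],
                         columns=regions._REGION_COLS)
        art = regions.intersect_artificial(a, f)
        assert (art["end"] - art["start"]).sum() <= (a["end"] - a["start"]).sum()
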