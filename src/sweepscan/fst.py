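"""Weir-Cockerham F_ST, observed heterozygosity and allele-frequency tracks.

The two-population unbiased estimator decomposes the allele-frequency
variance at each site into among-population (a), among-individual (b) and
within-individual (c) components; window estimates are the ratio of sums
sum(a) / sum(a + b + c) over the sites of each 10 kb window, the standard
multi-locus practice.  Per-site negative components are retained in the
sums.  Genotypes are reconstructed from consecutive haplotype row pairs,
so heterozygosity reflects the phased input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import PopulationMap, VariantTable, window_bounds, window_index

__all__ = ["wc_components", "window_fst", "window_het_and_freq", "fst_track"]


def _pool_site_stats(hm_pool: np.ndarray):
    """(n_i, p_i, h_i) per site for one pool's haplotype matrix."""
    n = hm_pool.shape[0] // 2
    g = hm_pool[0::2].astype(np.int64) + hm_pool[1::2]  # derived copies, 0/1/2
    p = g.sum(axis=0) / (2.0 * n)
    h = (g == 1).mean(axis=0)
    return n, p, h


def wc_components(hm_a: np.ndarray, hm_b: np.ndarray):
    """Per-site Weir-Cockerham variance components for two pools.

    Returns ``(a, b, c, usable)`` arrays; *usable* is False where the site
    is monomorphic across the union (components undefined there and set to 0).
    """
    n1, p1, h1 = _pool_site_stats(hm_a)
    n2, p2, h2 = _pool_site_stats(hm_b)
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1.0 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar) - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    usable = (p_bar > 0.0) & (p_bar < 1.0)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def theta_site(hm_a: np.ndarray, hm_b: np.ndarray) -> np.ndarray:
    """Per-site theta-hat = a / (a + b + c); NaN at unusable sites."""
    a, b, c, usable = wc_components(hm_a, hm_b)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        t = a / denom
    return np.where(usable & (denom != 0), t, np.nan)


def window_fst(a: np.ndarray, b: np.ndarray, c: np.ndarray, usable: np.ndarray,
               vt: VariantTable, width: int = 10_000) -> pd.DataFrame:
    """Ratio-of-sums window F_ST track (chrom, start, end, n_snps, value)."""
    df = pd.DataFrame({
        "chrom": vt.chrom, "win": window_index(vt.pos, width),
        "a": a, "abc": a + b + c, "usable": usable.astype(int),
    })
    df = df[df["usable"] == 1]
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "value"])
    grouped = df.groupby(["chrom", "win"], sort=False).agg(
        n_snps=("a", "size"), a_sum=("a", "sum"), abc_sum=("abc", "sum")
    ).reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        value = grouped["a_sum"] / grouped["abc_sum"]
    start, end = window_bounds(grouped["win"].to_numpy(), width)
    out = pd.DataFrame({
        "chrom": grouped["chrom"], "start": start, "end": end,
        "n_snps": grouped["n_snps"], "value": value,
    }).dropna(subset=["value"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def fst_track(hm: np.ndarray, vt: VariantTable, pm: PopulationMap, pool,
              individual_ids, width: int = 10_000,
              reference: str | None = None) -> pd.DataFrame:
    """Window F_ST between *pool* and the reference pool (or *reference*)."""
    from .genotype_io import pool_haplotypes

    ref = reference if reference is not None else pm.reference_pool
    hm_a = pool_haplotypes(hm, pm, pool, individual_ids)
    hm_b = pool_haplotypes(hm, pm, ref, individual_ids)
    a, b, c, usable = wc_components(hm_a, hm_b)
    return window_fst(a, b, c, usable, vt, width)


def window_het_and_freq(hm: np.ndarray, vt: VariantTable, pm: PopulationMap,
                        pool: str, individual_ids,
                        width: int = 10_000) -> pd.DataFrame:
    """Observed heterozygosity and major-allele-frequency window track of one pool.

    The major allele is the observed pool's per-site major allele; the
    ``freq_<other>`` columns report that same allele's frequency in every
    other pool, so trajectories are comparable across pools.
    """
    from .genotype_io import pool_haplotypes

    sub = pool_haplotypes(hm, pm, pool, individual_ids)
    n = sub.shape[0] // 2
    g = sub[0::2].astype(np.int64) + sub[1::2]
    het = (g == 1).mean(axis=0)
    freq1 = g.sum(axis=0) / (2.0 * n)
    major_is_derived = freq1 > 0.5
    major_freq = np.where(major_is_derived, freq1, 1.0 - freq1)

    others = {}
    for other in pm.pools:
        if other == pool:
            continue
        o = pool_haplotypes(hm, pm, other, individual_ids)
        f1 = o.mean(axis=0)
        others[f"freq_{other}"] = np.where(major_is_derived, f1, 1.0 - f1)

    df = pd.DataFrame({"chrom": vt.chrom, "win": window_index(vt.pos, width),
                       "het": het, "major_freq": major_freq, **others})
    agg = {"het": ("het", "mean"), "major_freq": ("major_freq", "mean"),
           "n_snps": ("het", "size")}
    for k in others:
        agg[k] = (k, "mean")
    grouped = df.groupby(["chrom", "win"], sort=False).agg(**agg).reset_index()
    start, end = window_bounds(grouped["win"].to_numpy(), width)
    cols = {"chrom": grouped["chrom"], "start": start, "end": end,
            "n_snps": grouped["n_snps"], "het": grouped["het"],
            "major_freq": grouped["major_freq"]}
    for k in others:
        cols[k] = grouped[k]
    return (pd.DataFrame(cols)
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True))
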