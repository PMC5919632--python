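"""Permutation thresholds, outlier calling and the 200 kb region calculus.

Significance is empirical: each statistic's genome-wide null is built by
permutation (1,000 by default), the threshold is the 95th percentile of
the pooled permuted window values, and outliers are windows strictly
above it.  What exactly is permuted preserves each statistic's marginal
distribution while destroying its spatial signal:

* F_ST   - individual pool labels are shuffled between the two pools;
* |iHS|  - per-site scores are shuffled across site positions genome-wide;
* CLR    - derived counts are shuffled across site positions within each
           chromosome and the grid scan is re-run (100 permutations by
           default for runtime; overridable to 1,000).

Each outlier window's midpoint, padded by +/-100 kb, becomes a potential
selection region (PSR); same-method regions that touch are merged, iHS
and CLR regions closer than 200 kb are merged into iHS-CLR regions, and
an iHS-CLR region overlapping an F_ST region by at least 1 bp is kept, in
full extent, as an artificial-selection region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PopulationMap, VariantTable, window_index
from . import clr as clr_mod
from . import fst as fst_mod
from . import ihs as ihs_mod

__all__ = [
    "ThresholdSpec",
    "permute_fst_null",
    "permute_ihs_null",
    "permute_clr_null",
    "permute_score_null",
    "call_outliers",
    "build_psr",
    "merge_regions",
    "merge_ihs_clr",
    "intersect_artificial",
]

REGION_PAD = 100_000  # bp each side of an outlier window midpoint
MERGE_GAP = 200_000  # bp, iHS-CLR merging distance


@dataclass
class ThresholdSpec:
    """An empirical 5% significance threshold and the null it came from."""

    method: str  # "ihs" | "clr" | "fst"
    n_permutations: int
    level: float
    threshold: float
    null_values: np.ndarray  # pooled permuted window values, sorted

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        self.null_values = np.sort(np.asarray(self.null_values, dtype=float))

    @property
    def null_size(self) -> int:
        return self.null_values.size

    def empirical_p(self, values) -> np.ndarray:
        """Fraction of the null >= each observed value."""
        v = np.atleast_1d(np.asarray(values, dtype=float))
        below = np.searchsorted(self.null_values, v, side="left")
        return (self.null_values.size - below) / self.null_values.size


def _quantile_threshold(null: np.ndarray, level: float) -> float:
    """(1 - level) linear-interpolation quantile of the pooled null."""
    return float(np.quantile(np.asarray(null, dtype=float), 1.0 - level))


def permute_fst_null(hm: np.ndarray, vt: VariantTable, pm: PopulationMap,
                     pool: str, individual_ids, n_perm: int = 1000,
                     seed: int = 0, level: float = 0.05,
                     width: int = 10_000) -> ThresholdSpec:
    """Null window-F_ST distribution from shuffling pool labels.

    Each permutation reassigns the union's individuals to two pools of the
    original sizes and recomputes the genome-wide window F_ST track.
    """
    from .genotype_io import pool_haplotypes

    ref = pm.reference_pool
    hm_a = pool_haplotypes(hm, pm, pool, individual_ids)
    hm_b = pool_haplotypes(hm, pm, ref, individual_ids)
    na, nb = hm_a.shape[0] // 2, hm_b.shape[0] // 2
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 individuals in each pool to permute")
    union = np.vstack([hm_a, hm_b]).reshape(na + nb, 2, -1)
    rng = np.random.default_rng(seed)
    null: list = []
    for _ in range(n_perm):
        order = rng.permutation(na + nb)
        pa = union[order[:na]].reshape(2 * na, -1)
        pb = union[order[na:]].reshape(2 * nb, -1)
        a, b, c, usable = fst_mod.wc_components(pa, pb)
        track = fst_mod.window_fst(a, b, c, usable, vt, width)
        null.append(track["value"].to_numpy())
    null = np.concatenate(null) if null else np.array([np.nan])
    return ThresholdSpec(method="fst", n_permutations=n_perm, level=level,
                         threshold=_quantile_threshold(null, level),
                         null_values=null)


def permute_ihs_null(ihs_df: pd.DataFrame, n_perm: int = 1000, seed: int = 0,
                     level: float = 0.05, width: int = 10_000) -> ThresholdSpec:
    """Null window-mean-|iHS| distribution from shuffling scores over positions."""
    rng = np.random.default_rng(seed)
    scores = ihs_df["ihs"].to_numpy().copy()
    null: list = []
    for _ in range(n_perm):
        perm = ihs_df.copy()
        perm["ihs"] = rng.permutation(scores)
        track = ihs_mod.window_abs_ihs(perm, width)
        null.append(track["value"].to_numpy())
    null = np.concatenate(null)
    return ThresholdSpec(method="ihs", n_permutations=n_perm, level=level,
                         threshold=_quantile_threshold(null, level),
                         null_values=null)


def permute_clr_null(hm: np.ndarray, vt: VariantTable, n_perm: int = 100,
                     seed: int = 0, level: float = 0.05, grid: int = 10_000,
                     flank: int = clr_mod.FLANK, refine: bool = False,
                     table=None) -> ThresholdSpec:
    """Null CLR distribution from shuffling derived counts within chromosomes."""
    rng = np.random.default_rng(seed)
    if table is None:
        table = clr_mod.SweepLikelihoodTable.build(clr_mod.background_sfs(hm))
    counts = hm.sum(axis=0).astype(np.int64)
    null: list = []
    for _ in range(n_perm):
        perm = counts.copy()
        for c in vt.chromosomes():
            sl = vt.chrom_slice(c)
            perm[sl] = rng.permutation(perm[sl])
        track = clr_mod.clr_scan(hm, vt, grid=grid, flank=flank, counts=perm,
                                 refine=refine, table=table)
        null.append(track["value"].to_numpy())
    null = np.concatenate(null)
    return ThresholdSpec(method="clr", n_permutations=n_perm, level=level,
                         threshold=_quantile_threshold(null, level),
                         null_values=null)


def permute_score_null(method: str, *args, **kwargs) -> ThresholdSpec:
    """Dispatch to the per-statistic permutation scheme by name."""
    if method == "ihs":
        return permute_ihs_null(*args, **kwargs)
    if method == "clr":
        return permute_clr_null(*args, **kwargs)
    if method == "fst":
        return permute_fst_null(*args, **kwargs)
    raise ValueError(f"unknown method {method!r}")


def call_outliers(track: pd.DataFrame, spec: ThresholdSpec) -> pd.DataFrame:
    """Windows whose value strictly exceeds the threshold, with empirical P."""
    if track.empty:
        out = track.copy()
        out["empirical_p"] = pd.Series(dtype=float)
        return out
    mask = track["value"].to_numpy() > spec.threshold
    out = track[mask].copy()
    out["empirical_p"] = spec.empirical_p(out["value"].to_numpy())
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# region calculus (0-based half-open intervals, BED-style)
# ---------------------------------------------------------------------------

_REGION_COLS = ["chrom", "start", "end", "tag", "n_windows", "best_stat", "empirical_p"]


def _empty_regions(tag: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=_REGION_COLS)
    return df.astype({"start": np.int64, "end": np.int64})


def merge_regions(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge overlapping / book-ended regions (or within *gap* bp), per chromosome."""
    if df.empty:
        return df.reset_index(drop=True)
    df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    rows = []
    cur = None
    for rec in df.itertuples(index=False):
        if cur is not None and rec.chrom == cur["chrom"] and rec.start <= cur["end"] + gap:
            cur["end"] = max(cur["end"], rec.end)
            cur["n_windows"] += rec.n_windows
            if rec.best_stat > cur["best_stat"]:
                cur["best_stat"] = rec.best_stat
                cur["empirical_p"] = rec.empirical_p
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": rec.chrom, "start": int(rec.start), "end": int(rec.end),
                   "tag": rec.tag, "n_windows": int(rec.n_windows),
                   "best_stat": float(rec.best_stat),
                   "empirical_p": float(rec.empirical_p)}
    rows.append(cur)
    return pd.DataFrame(rows, columns=_REGION_COLS)


def build_psr(outliers: pd.DataFrame, tag: str, pad: int = REGION_PAD,
              chrom_lengths: dict | None = None) -> pd.DataFrame:
    """200 kb potential selection regions around outlier windows.

    Each outlier window's midpoint is extended by *pad* bp each side,
    clipped to ``[0, chromosome length)``, and same-method regions that
    overlap or touch are merged.
    """
    if outliers.empty:
        return _empty_regions(tag)
    mid = (outliers["start"].to_numpy() + outliers["end"].to_numpy()) // 2
    start = np.maximum(mid - pad, 0)
    end = mid + pad
    if chrom_lengths:
        limit = np.array([chrom_lengths.get(c, np.iinfo(np.int64).max)
                          for c in outliers["chrom"]], dtype=np.int64)
        end = np.minimum(end, limit)
    df = pd.DataFrame({
        "chrom": outliers["chrom"].to_numpy(), "start": start, "end": end,
        "tag": tag, "n_windows": 1,
        "best_stat": outliers["value"].to_numpy(),
        "empirical_p": outliers["empirical_p"].to_numpy()
        if "empirical_p" in outliers else np.nan,
    })
    return merge_regions(df)


def merge_ihs_clr(psr_ihs: pd.DataFrame, psr_clr: pd.DataFrame,
                  gap: int = MERGE_GAP) -> pd.DataFrame:
    """Union of the iHS and CLR region sets, merging regions within *gap* bp."""
    parts = [df for df in (psr_ihs, psr_clr) if not df.empty]
    if not parts:
        return _empty_regions("IHS_CLR")
    both = pd.concat(parts, ignore_index=True)
    tags = sorted(set(psr_ihs["tag"]) | set(psr_clr["tag"]))
    both = both.assign(tag="+".join(tags) if tags else "IHS_CLR")
    merged = merge_regions(both, gap=gap)
    merged["tag"] = "IHS_CLR"
    return merged


def intersect_artificial(ihs_clr: pd.DataFrame, fst_regions: pd.DataFrame) -> pd.DataFrame:
    """iHS-CLR regions overlapping (>= 1 bp) an F_ST region, kept in full extent."""
    if ihs_clr.empty or fst_regions.empty:
        return _empty_regions("ARTIFICIAL")
    keep = []
    for rec in ihs_clr.itertuples(index=False):
        f = fst_regions[fst_regions["chrom"] == rec.chrom]
        if ((f["start"].to_numpy() < rec.end) & (f["end"].to_numpy() > rec.start)).any():
            keep.append(rec)
    if not keep:
        return _empty_regions("ARTIFICIAL")
    out = pd.DataFrame(keep, columns=ihs_clr.columns)
    out["tag"] = "ARTIFICIAL"
    return out.reset_index(drop=True)


def write_bed(path, regions: pd.DataFrame) -> None:
    """BED (0-based half-open) with tag, window count, best statistic, empirical P."""
    regions.to_csv(path, sep="\t", header=True, index=False)
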