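"""Extended haplotype homozygosity (EHH) and unstandardized iHS.

At a core SNP, the EHH of an allele at a flanking marker is the
probability that two random carrier haplotypes are identical at every
marker from the core out to that marker.  iHH is the area under the EHH
curve over physical distance (bp), and

    iHS = ln(iHH_ancestral / iHH_derived)

is used unstandardized: the genome-wide picture is taken by averaging
|iHS| in non-overlapping 10 kb windows, and significance comes from a
permutation threshold rather than from frequency-bin standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import VariantTable, window_index, window_bounds

log = logging.getLogger(__name__)

__all__ = ["EHHProfile", "ehh_curve", "ihs_site", "ihs_scan", "window_abs_ihs"]

#: EHH level below which the curve is truncated (rehh convention)
EHH_CUTOFF = 0.05
#: minimum minor-allele frequency of a usable core SNP
MAF_CORE = 0.05
#: extension guard, bp each side, bounding worst-case runtime
MAX_EXTEND = 1_000_000


@dataclass
class EHHProfile:
    core: int
    allele: int  # 0 = ancestral, 1 = derived
    positions: np.ndarray  # bp, ascending, includes the core position
    ehh: np.ndarray  # same length; 1.0 at the core
    core_index: int = 0  # index of the core within the arrays


def _side_ehh(sub: np.ndarray, order: np.ndarray, cutoff: float) -> tuple:
    """EHH values walking outward through columns *order* of carrier rows *sub*.

    Stops after the first value below *cutoff* (that value is returned) or
    when the markers run out.
    """
    n = sub.shape[0]
    denom = n * (n - 1) / 2.0
    groups = np.zeros(n, dtype=np.int64)
    out = []
    for t in order:
        # refine identity groups by the allele at marker t
        _, groups = np.unique(groups * 2 + sub[:, t], return_inverse=True)
        counts = np.bincount(groups)
        ehh = float((counts * (counts - 1) / 2.0).sum() / denom)
        out.append(ehh)
        if ehh < cutoff:
            break
    return np.array(out)


def ehh_curve(hm: np.ndarray, vt: VariantTable, core: int, allele: int,
              cutoff: float = EHH_CUTOFF, max_extend: int = MAX_EXTEND) -> EHHProfile:
    """EHH profile of one core allele, extended left and right until *cutoff*.

    Raises ``ValueError`` when fewer than two haplotypes carry the allele.
    """
    carriers = np.flatnonzero(hm[:, core] == allele)
    if carriers.size < 2:
        raise ValueError(f"fewer than 2 carriers of allele {allele} at site {core}")
    sl = vt.chrom_slice(vt.chrom[core])
    sub = hm[carriers]
    pos = vt.pos
    lo = np.searchsorted(pos[sl.start:sl.stop], pos[core] - max_extend) + sl.start
    hi = np.searchsorted(pos[sl.start:sl.stop], pos[core] + max_extend, side="right") + sl.start
    right = np.arange(core + 1, hi)
    left = np.arange(lo, core)[::-1]
    e_r = _side_ehh(sub, right, cutoff)
    e_l = _side_ehh(sub, left, cutoff)
    positions = np.concatenate([pos[left[:e_l.size]][::-1], [pos[core]],
                                pos[right[:e_r.size]]])
    ehh = np.concatenate([e_l[::-1], [1.0], e_r])
    return EHHProfile(core=core, allele=allele, positions=positions, ehh=ehh,
                      core_index=int(e_l.size))


def _ihh(profile: EHHProfile, cutoff: float) -> float:
    """Trapezoidal area (bp) under the EHH curve, truncated at the cutoff.

    Only segments whose two endpoints both sit at or above the cutoff
    contribute; the curve is considered to end at the last such marker.
    """
    pos = profile.positions.astype(float)
    ehh = profile.ehh
    core = profile.core_index
    area = 0.0
    for step in (-1, 1):
        i = core
        while 0 <= i + step < pos.size:
            j = i + step
            if ehh[j] < cutoff:
                break
            area += abs(pos[j] - pos[i]) * (ehh[i] + ehh[j]) / 2.0
            i = j
    return area


def ihs_site(hm: np.ndarray, vt: VariantTable, core: int,
             cutoff: float = EHH_CUTOFF, maf_core: float = MAF_CORE,
             max_extend: int = MAX_EXTEND):
    """(iHH_A, iHH_D, unstandardized iHS) at one core SNP, or None if unusable.

    A core is unusable when its MAF is below *maf_core*, either allele has
    fewer than two carriers, or either integral vanishes.
    """
    col = hm[:, core]
    p = col.mean()
    if min(p, 1 - p) < maf_core:
        return None
    if (col == 0).sum() < 2 or (col == 1).sum() < 2:
        return None
    prof_a = ehh_curve(hm, vt, core, 0, cutoff, max_extend)
    prof_d = ehh_curve(hm, vt, core, 1, cutoff, max_extend)
    ihh_a = _ihh(prof_a, cutoff)
    ihh_d = _ihh(prof_d, cutoff)
    if ihh_a <= 0 or ihh_d <= 0:
        return None
    return ihh_a, ihh_d, float(np.log(ihh_a / ihh_d))


def ihs_scan(hm: np.ndarray, vt: VariantTable, cutoff: float = EHH_CUTOFF,
             maf_core: float = MAF_CORE, max_extend: int = MAX_EXTEND) -> pd.DataFrame:
    """Per-site unstandardized iHS table (chrom, pos, iHH_A, iHH_D, ihs)."""
    rows = []
    n_skipped = 0
    for core in range(len(vt)):
        res = ihs_site(hm, vt, core, cutoff, maf_core, max_extend)
        if res is None:
            n_skipped += 1
            continue
        ihh_a, ihh_d, ihs = res
        rows.append((vt.chrom[core], int(vt.pos[core]), ihh_a, ihh_d, ihs))
    if n_skipped:
        log.info("iHS: skipped %d sites (low MAF, <2 carriers or zero integral)",
                 n_skipped)
    return pd.DataFrame(rows, columns=["chrom", "pos", "iHH_A", "iHH_D", "ihs"])


def window_abs_ihs(ihs_df: pd.DataFrame, width: int = 10_000) -> pd.DataFrame:
    """Mean |iHS| in non-overlapping windows tiling each chromosome from position 1.

    Windows containing no scored site are omitted.  Returns columns
    ``chrom, start, end, n_snps, value`` (start/end 0-based half-open).
    """
    if ihs_df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "value"])
    df = ihs_df.copy()
    df["win"] = window_index(df["pos"].to_numpy(), width)
    grouped = (
        df.assign(abs_ihs=df["ihs"].abs())
        .groupby(["chrom", "win"], sort=False)
        .agg(n_snps=("abs_ihs", "size"), value=("abs_ihs", "mean"))
        .reset_index()
    )
    start, end = window_bounds(grouped["win"].to_numpy(), width)
    out = pd.DataFrame({
        "chrom": grouped["chrom"], "start": start, "end": end,
        "n_snps": grouped["n_snps"], "value": grouped["value"],
    })
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
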