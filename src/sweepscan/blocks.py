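"""Solid-spine haplotype blocks and hard/soft sweep classification.

Inside each artificial-selection region, haplotype blocks are inferred
from the pooled domestic haplotypes with the solid-spine-of-LD rule: a
run of markers [i..j] is a block when the first and the last marker each
have |D'| >= 0.8 with every marker between them.  A block haplotype at
frequency > 0.8 in the observed domestic pool is a core haplotype; its
exact frequency in the wild reference pool decides the sweep mode:

* 0            -> hard sweep (de novo allele, absent in the reference);
* > 0.125      -> soft sweep (standing variation; the floor corresponds
                  to at least 4 of the 32 reference gametes);
* (0, 0.125]   -> unclassified.

A region with several blocks is classified hard if any block is hard,
else soft if any is soft, else unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import VariantTable
from .ld import dprime_matrix

__all__ = [
    "HaploBlock",
    "SweepCall",
    "soft_sweep_frequency_floor",
    "solid_spine_blocks",
    "core_haplotypes",
    "classify_sweep",
    "classify_region",
]

DPRIME_MIN = 0.8
CORE_FREQ_MIN = 0.8
SOFT_FREQ_FLOOR = 0.125
#: span cap for spine blocks.  On pooled haplotypes of differentiated pools
#: |D'| stays high at arbitrary distance (admixture LD), so an uncapped
#: spine fuses whole regions; blocks are bounded by the scale over which
#: within-population LD decays (tens of kb for dense SNP data).
MAX_BLOCK_SPAN = 50_000  # bp


def soft_sweep_frequency_floor(min_gametes: int = 4, n_diploid_reference: int = 16) -> float:
    """Minimum reference-pool frequency for a standing (soft-sweep) allele.

    Requiring at least *min_gametes* carrier gametes among the reference
    pool's ``2 * n_diploid_reference`` gametes gives 4 / 32 = 0.125 for a
    16-individual wild reference.
    """
    return min_gametes / (2.0 * n_diploid_reference)


@dataclass
class HaploBlock:
    chrom: str
    markers: np.ndarray  # marker indices into the VariantTable, ascending
    positions: np.ndarray
    #: pool label -> {haplotype string: frequency}; frequencies sum to 1
    frequencies: dict = field(default_factory=dict)

    @property
    def first(self) -> int:
        return int(self.markers[0])

    @property
    def last(self) -> int:
        return int(self.markers[-1])

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def span(self) -> tuple:
        return int(self.positions[0]), int(self.positions[-1])


@dataclass
class SweepCall:
    chrom: str
    start: int
    end: int
    core: str
    freq_domestic: float
    freq_reference: float
    classification: str  # "hard" | "soft" | "unclassified"


def _haplotype_freqs(sub: np.ndarray) -> dict:
    """Frequency of each distinct haplotype string over the block columns."""
    strings = ["".join(map(str, row)) for row in sub]
    out: dict = {}
    for s in strings:
        out[s] = out.get(s, 0) + 1
    total = len(strings)
    return {s: c / total for s, c in out.items()}


def solid_spine_blocks(hm: np.ndarray, vt: VariantTable, region,
                       dprime_min: float = DPRIME_MIN,
                       max_span: int = MAX_BLOCK_SPAN) -> list:
    """Solid-spine blocks over the markers inside *region*.

    *region* is ``(chrom, start, end)`` in 0-based half-open bp; *hm* holds
    the pooled domestic haplotypes.  Markers monomorphic in *hm* have no
    defined |D'| and are excluded from block inference (blocks may span
    across them).  Blocks are found greedily left to right, preferring
    longer spans, and never overlap.
    """
    chrom, start, end = region
    sl = vt.chrom_slice(chrom)
    pos = vt.pos[sl]
    lo = int(np.searchsorted(pos, start + 1)) + sl.start  # 1-based pos in (start, end]
    hi = int(np.searchsorted(pos, end, side="right")) + sl.start
    idx = np.arange(lo, hi)
    freq = hm[:, idx].mean(axis=0) if idx.size else np.array([])
    idx = idx[(freq > 0) & (freq < 1)]
    if idx.size < 2:
        return []
    dp = dprime_matrix(hm[:, idx])
    m = idx.size
    strong = dp >= dprime_min  # NaN compares False
    blocks = []
    i = 0
    while i < m - 1:
        best_j = -1
        for j in range(i + 1, m):
            if vt.pos[idx[j]] - vt.pos[idx[i]] > max_span:
                break
            # spine: first and last marker each in strong LD with all between
            inner = slice(i + 1, j + 1)
            if strong[i, inner].all() and strong[j, i:j].all():
                best_j = j
        if best_j > 0:
            blocks.append(HaploBlock(
                chrom=chrom, markers=idx[i:best_j + 1].copy(),
                positions=vt.pos[idx[i:best_j + 1]].copy(),
            ))
            i = best_j + 1
        else:
            i += 1
    return blocks


def block_frequencies(block: HaploBlock, pools: dict) -> None:
    """Fill ``block.frequencies`` from pool-label -> haplotype-matrix mapping."""
    block.frequencies = {label: _haplotype_freqs(hm[:, block.markers])
                         for label, hm in pools.items()}


def core_haplotypes(block: HaploBlock, pool: str,
                    freq_min: float = CORE_FREQ_MIN) -> list:
    """Block haplotypes at frequency strictly greater than *freq_min* in *pool*."""
    freqs = block.frequencies.get(pool)
    if freqs is None:
        raise KeyError(f"no frequencies computed for pool {pool!r}")
    return [(s, f) for s, f in freqs.items() if f > freq_min]


def classify_sweep(block: HaploBlock, core: str, freq_domestic: float,
                   reference_pool: str,
                   soft_floor: float = SOFT_FREQ_FLOOR) -> SweepCall:
    """Classify one core haplotype by its exact frequency in the reference pool."""
    ref_freqs = block.frequencies.get(reference_pool)
    if ref_freqs is None:
        raise ValueError(f"reference pool {reference_pool!r} lacks block frequencies")
    f_ref = ref_freqs.get(core, 0.0)
    if f_ref == 0.0:
        cls = "hard"
    elif f_ref > soft_floor:
        cls = "soft"
    else:
        cls = "unclassified"
    lo, hi = block.span
    return SweepCall(chrom=block.chrom, start=lo - 1, end=hi, core=core,
                     freq_domestic=freq_domestic, freq_reference=f_ref,
                     classification=cls)


def classify_region(hm_domestic: np.ndarray, hm_reference: np.ndarray,
                    vt: VariantTable, region, domestic_label: str = "domestic",
                    reference_label: str = "reference",
                    dprime_min: float = DPRIME_MIN,
                    core_freq_min: float = CORE_FREQ_MIN,
                    soft_floor: float = SOFT_FREQ_FLOOR,
                    max_span: int = MAX_BLOCK_SPAN,
                    hm_spine: np.ndarray | None = None):
    """Blocks, cores and the region-level class for one candidate region.

    Block boundaries come from *hm_spine* (all domestic pools pooled, so a
    sweep fixed in the observed pool is still polymorphic there); core
    frequencies come from *hm_domestic* (the observed pool) and the
    reference pool.  When *hm_spine* is omitted the observed pool is used.

    Returns ``(calls, region_class)`` where *calls* is the per-core
    :class:`SweepCall` list and *region_class* is hard if any call is hard,
    else soft if any is soft, else unclassified.
    """
    if hm_spine is None:
        hm_spine = hm_domestic
    blocks = solid_spine_blocks(hm_spine, vt, region, dprime_min, max_span)
    calls = []
    for block in blocks:
        block_frequencies(block, {domestic_label: hm_domestic,
                                  reference_label: hm_reference})
        for core, f_dom in core_haplotypes(block, domestic_label, core_freq_min):
            calls.append(classify_sweep(block, core, f_dom, reference_label,
                                        soft_floor))
    classes = [c.classification for c in calls]
    if "hard" in classes:
        region_class = "hard"
    elif "soft" in classes:
        region_class = "soft"
    else:
        region_class = "unclassified"
    return calls, region_class
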