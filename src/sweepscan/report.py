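"""Summary arithmetic over per-pool region inventories.

For each domestic pool the scan yields a set of positive-selection regions
(iHS-CLR) and the subset confirmed as artificial selection by F_ST
overlap.  The headline numbers are the per-pool percentages

    count_fraction  = 100 * n_artificial / n_positive
    length_fraction = 100 * span_artificial / span_positive

rounded half-up to 2 decimals, their range, and their mean across pools
(reported at integer precision for counts and one decimal for lengths).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["PoolSummary", "selection_fractions", "summarize_pools"]


@dataclass
class PoolSummary:
    pool: str
    n_positive_regions: int
    positive_span_mb: float
    n_artificial_regions: int
    artificial_span_mb: float

    def __post_init__(self) -> None:
        if self.n_artificial_regions > self.n_positive_regions:
            raise ValueError("artificial region count exceeds positive count")
        if self.artificial_span_mb > self.positive_span_mb + 1e-9:
            raise ValueError("artificial span exceeds positive span")


def _round(x: float, places: int) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def selection_fractions(summaries: list) -> dict:
    """Per-pool percentages plus min / max / mean for counts and spans.

    Returns a dict with a per-pool table and the aggregate fields
    ``count_min/max/mean_pct`` and ``length_min/max/mean_pct``; the means
    are rounded to integer (counts) and 1 decimal (lengths).
    """
    if not summaries:
        raise ValueError("no pool summaries given")
    rows = []
    for s in summaries:
        if s.n_positive_regions == 0 or s.positive_span_mb == 0:
            raise ValueError(f"pool {s.pool}: zero positive regions or span")
        rows.append({
            "pool": s.pool,
            "count_fraction_pct": _round(
                100.0 * s.n_artificial_regions / s.n_positive_regions, 2),
            "length_fraction_pct": _round(
                100.0 * s.artificial_span_mb / s.positive_span_mb, 2),
        })
    table = pd.DataFrame(rows)
    counts = table["count_fraction_pct"]
    lengths = table["length_fraction_pct"]
    return {
        "per_pool": table,
        "count_min_pct": float(counts.min()),
        "count_max_pct": float(counts.max()),
        "count_mean_pct": _round(float(counts.mean()), 0),
        "length_min_pct": float(lengths.min()),
        "length_max_pct": float(lengths.max()),
        "length_mean_pct": _round(float(lengths.mean()), 1),
    }


def summarize_pools(positive: dict, artificial: dict) -> list:
    """Build :class:`PoolSummary` records from per-pool region DataFrames."""
    out = []
    for pool, pos_regions in positive.items():
        art_regions = artificial.get(pool)
        pos_span = float((pos_regions["end"] - pos_regions["start"]).sum()) / 1e6
        art_span = (float((art_regions["end"] - art_regions["start"]).sum()) / 1e6
                    if art_regions is not None and not art_regions.empty else 0.0)
        out.append(PoolSummary(
            pool=pool,
            n_positive_regions=len(pos_regions),
            positive_span_mb=pos_span,
            n_artificial_regions=0 if art_regions is None else len(art_regions),
            artificial_span_mb=art_span,
        ))
    return out
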