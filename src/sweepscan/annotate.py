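"""Gene-model annotation: SNP component classes and genes in regions.

Gene and exon features are read from GFF3 or GTF (via gffutils), stored
as 0-based half-open intervals.  A SNP is exonic if it falls inside any
exon, else intronic if inside any gene span, else intergenic; overlap is
strand-agnostic and the precedence is exonic > intronic > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import VariantTable

__all__ = ["GeneModel", "load_gene_models", "classify_snp_location", "genes_in_regions"]


@dataclass
class GeneModel:
    gene_id: str
    name: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    exons: list = field(default_factory=list)  # (start, end) half-open, merged


def _merge_intervals(spans: list) -> list:
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def load_gene_models(path) -> list:
    """Parse a GFF3 or GTF file into :class:`GeneModel` records.

    Exons are attached to their gene via Parent/gene_id attributes and
    merged; gene spans missing an explicit gene feature are inferred from
    their exons.  Malformed lines raise ``ValueError`` with the line number.
    """
    import gffutils

    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique",
                                disable_infer_genes=False,
                                disable_infer_transcripts=False)
    except Exception as exc:  # surface the gffutils parse position if present
        raise ValueError(f"failed to parse gene models from {path}: {exc}") from exc

    genes: dict = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", feat.attributes.get("ID", [feat.id]))[0]
        name = feat.attributes.get("gene_name", feat.attributes.get("Name", [gid]))[0]
        genes[gid] = GeneModel(gene_id=gid, name=name, chrom=feat.seqid,
                               start=feat.start - 1, end=feat.end,
                               strand=feat.strand or ".")
    for feat in db.features_of_type("exon"):
        parents = [g.id for g in db.parents(feat, featuretype="gene")]
        if not parents:
            parents = feat.attributes.get("gene_id", [])
        for pid in parents:
            gid = pid
            if gid not in genes:
                # GTF without explicit gene lines: grow the gene from exons
                name = feat.attributes.get("gene_name", [gid])[0]
                genes[gid] = GeneModel(gene_id=gid, name=name, chrom=feat.seqid,
                                       start=feat.start - 1, end=feat.end,
                                       strand=feat.strand or ".")
            g = genes[gid]
            g.exons.append((feat.start - 1, feat.end))
            g.start = min(g.start, feat.start - 1)
            g.end = max(g.end, feat.end)
    for g in genes.values():
        g.exons = _merge_intervals(g.exons)
    return sorted(genes.values(), key=lambda g: (str(g.chrom), g.start, g.end))


def _interval_arrays(spans_by_chrom: dict):
    """Per-chromosome sorted boundary arrays for membership queries."""
    out = {}
    for c, spans in spans_by_chrom.items():
        merged = _merge_intervals(spans)
        out[c] = (np.array([s for s, _ in merged], dtype=np.int64),
                  np.array([e for _, e in merged], dtype=np.int64))
    return out


def _inside(starts: np.ndarray, ends: np.ndarray, x: np.ndarray) -> np.ndarray:
    i = np.searchsorted(starts, x, side="right") - 1
    i = np.clip(i, 0, max(starts.size - 1, 0))
    return (starts.size > 0) & (x >= starts[i]) & (x < ends[i])


def classify_snp_location(vt: VariantTable, genes: list) -> pd.DataFrame:
    """Per-SNP category (exonic > intronic > intergenic), strand-agnostic.

    Returns columns ``snp_id, chrom, pos, category``.
    """
    exon_spans: dict = {}
    gene_spans: dict = {}
    for g in genes:
        gene_spans.setdefault(g.chrom, []).append((g.start, g.end))
        exon_spans.setdefault(g.chrom, []).extend(g.exons)
    exon_iv = _interval_arrays(exon_spans)
    gene_iv = _interval_arrays(gene_spans)
    cat = np.full(len(vt), "intergenic", dtype=object)
    x_all = vt.pos - 1  # to 0-based
    for c in vt.chromosomes():
        mask = vt.chrom == c
        x = x_all[mask]
        in_gene = np.zeros(x.size, dtype=bool)
        in_exon = np.zeros(x.size, dtype=bool)
        if c in gene_iv:
            in_gene = _inside(*gene_iv[c], x)
        if c in exon_iv and exon_iv[c][0].size:
            in_exon = _inside(*exon_iv[c], x)
        cc = np.where(in_exon, "exonic", np.where(in_gene, "intronic", "intergenic"))
        cat[mask] = cc
    return pd.DataFrame({"snp_id": vt.snp_id, "chrom": vt.chrom,
                         "pos": vt.pos, "category": cat})


def genes_in_regions(regions: pd.DataFrame, genes: list, pad: int = 0) -> dict:
    """Genes overlapping each region by >= 1 bp (after optional padding).

    Keys are ``(chrom, start, end)`` tuples; values are position-sorted
    gene-id lists.
    """
    out: dict = {}
    for rec in regions.itertuples(index=False):
        lo = max(int(rec.start) - pad, 0)
        hi = int(rec.end) + pad
        hits = [g for g in genes
                if g.chrom == rec.chrom and g.start < hi and g.end > lo]
        out[(rec.chrom, int(rec.start), int(rec.end))] = [
            g.gene_id for g in sorted(hits, key=lambda g: (g.start, g.end))
        ]
    return out
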