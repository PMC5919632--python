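"""Reading, QC and ancestral coding of phased genotype data.

Supported inputs are phased VCF 4.x and white-space separated PLINK
ped/map text, plus a two-column population map (``individual_id<TAB>pool``)
headed by a ``#reference=<pool>`` directive naming the wild reference pool.

The pipeline consumes already-phased data; an optional per-pool
major-allele fill for residual missing calls is provided, but no
imputation or phasing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import PopulationMap, QCConfig, VariantTable

log = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_vcf",
    "read_plink_text",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "hwe_exact_p",
    "apply_qc",
    "QCReport",
    "derive_ancestral_coding",
    "pool_haplotypes",
    "fill_missing",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str | None = None):
    """Read phased genotypes; returns ``(VariantTable, haplotypes, individual_ids)``.

    ``format`` is ``"vcf"`` or ``"plink-text"``; when omitted it is guessed
    from the file suffix (``.ped`` implies PLINK text, anything else VCF).
    Haplotype rows are ordered ``(ind1.hapA, ind1.hapB, ind2.hapA, ...)``.
    Multiallelic and unplaced records are dropped with a logged count.
    """
    path = Path(path)
    if format is None:
        format = "plink-text" if path.suffix == ".ped" else "vcf"
    if format == "vcf":
        return read_vcf(path)
    if format == "plink-text":
        return read_plink_text(path)
    raise ValueError(f"unknown genotype format {format!r}")


def read_vcf(path):
    """Read a phased VCF into a variant table and haplotype matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    n = len(individual_ids)
    chrom, pos, snp_id, a0, a1 = [], [], [], [], []
    columns = []
    n_multi = n_unplaced = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if rec.POS <= 0 or rec.CHROM in (".", ""):
            n_unplaced += 1
            continue
        col = np.empty(2 * n, dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            if len(g) != 3:
                raise ValueError(
                    f"non-diploid genotype for sample {individual_ids[i]} at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            ga, gb, phased = g
            if not phased and not (ga == gb or (ga < 0 and gb < 0)):
                raise ValueError(
                    f"unphased heterozygote for sample {individual_ids[i]} at "
                    f"{rec.CHROM}:{rec.POS}; phased input required"
                )
            col[2 * i] = ga if ga >= 0 else -1
            col[2 * i + 1] = gb if gb >= 0 else -1
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        snp_id.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}")
        a0.append(rec.REF)
        a1.append(rec.ALT[0])
        columns.append(col)
    if n_multi or n_unplaced:
        log.info("dropped %d multiallelic and %d unplaced records", n_multi, n_unplaced)
    if not columns:
        raise ValueError(f"no usable biallelic records in {path}")
    hm = np.column_stack(columns).astype(np.int8)
    vt = VariantTable(chrom=chrom, pos=pos, snp_id=snp_id, allele0=a0, allele1=a1)
    vt.validate()
    return vt, hm, individual_ids


def read_plink_text(ped_path, map_path=None):
    """Read white-space separated ped/map text (A/C/G/T alleles, phased columns).

    The two allele columns of each marker are taken as the two phased
    haplotypes of the individual; ``0`` codes a missing allele.
    """
    ped_path = Path(ped_path)
    if map_path is None:
        map_path = ped_path.with_suffix(".map")
    chrom, snp_id, pos = [], [], []
    with open(map_path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            chrom.append(f[0])
            snp_id.append(f[1])
            pos.append(int(f[3]))
    m = len(pos)
    individual_ids = []
    rows = []
    with open(ped_path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + 2 * m:
                raise ValueError(
                    f"ped line for {f[1] if len(f) > 1 else '?'} has {len(f) - 6} "
                    f"allele fields, expected {2 * m}"
                )
            individual_ids.append(f[1])
            rows.append(f[6:])
    alleles = np.array(rows, dtype=object).reshape(len(rows), m, 2)
    a0 = np.empty(m, dtype=object)
    a1 = np.empty(m, dtype=object)
    hm = np.empty((2 * len(rows), m), dtype=np.int8)
    for j in range(m):
        seen = [a for a in dict.fromkeys(alleles[:, j, :].ravel()) if a != "0"]
        if len(seen) > 2:
            raise ValueError(f"marker {snp_id[j]} has more than two alleles")
        a0[j] = seen[0] if seen else "0"
        a1[j] = seen[1] if len(seen) > 1 else a0[j]
        for i in range(len(rows)):
            for k in (0, 1):
                a = alleles[i, j, k]
                hm[2 * i + k, j] = -1 if a == "0" else (0 if a == a0[j] else 1)
    vt = VariantTable(chrom=chrom, pos=pos, snp_id=snp_id, allele0=list(a0), allele1=list(a1))
    # ped/map markers may be unsorted; sort to the internal convention
    order = np.lexsort((vt.pos, np.array([str(c) for c in vt.chrom], dtype=object)))
    if not np.array_equal(order, np.arange(m)):
        vt, hm = vt.subset(order), hm[:, order]
    vt.validate()
    return vt, hm, individual_ids


def write_vcf(path, vt: VariantTable, hm: np.ndarray, individual_ids) -> None:
    """Write a minimal phased VCF 4.2 readable by :func:`read_vcf`."""
    n = len(individual_ids)
    if hm.shape != (2 * n, len(vt)):
        raise ValueError("haplotype matrix shape does not match table/individuals")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in vt.chromosomes():
            end = int(vt.pos[vt.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={end + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in individual_ids)
            + "\n"
        )
        for j in range(len(vt)):
            gts = []
            for i in range(n):
                a, b = hm[2 * i, j], hm[2 * i + 1, j]
                gts.append(f"{'.' if a < 0 else a}|{'.' if b < 0 else b}")
            fh.write(
                f"{vt.chrom[j]}\t{vt.pos[j]}\t{vt.snp_id[j]}\t{vt.allele0[j]}\t"
                f"{vt.allele1[j]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_population_map(path) -> PopulationMap:
    """Read a two-column TSV (individual_id, pool) with a ``#reference=`` directive."""
    reference = None
    pool_of: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#reference="):
                reference = line.split("=", 1)[1].strip()
                continue
            if line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0].lower() in ("individual_id", "individual", "id", "sample"):
                continue
            if len(f) < 2:
                raise ValueError(f"population map line lacks a pool column: {raw!r}")
            if f[0] in pool_of:
                raise ValueError(f"individual {f[0]!r} listed twice in population map")
            pool_of[f[0]] = f[1]
    if reference is None:
        raise ValueError("population map lacks the '#reference=<pool>' directive")
    return PopulationMap(pool_of=pool_of, reference_pool=reference)


def write_population_map(path, pm: PopulationMap) -> None:
    with open(path, "w") as fh:
        fh.write(f"#reference={pm.reference_pool}\n")
        fh.write("individual_id\tpool\n")
        for ind, pool in pm.pool_of.items():
            fh.write(f"{ind}\t{pool}\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided Hardy-Weinberg exact-test p-value from genotype counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (the standard SNP exact test).
    """
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0
    # unnormalized P(het = h) via the recurrence
    #   P(h+2)/P(h) = 4 * hom_minor(h) * hom_major(h) / ((h+2)*(h+1))
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    probs = np.empty(hets.size, dtype=float)
    probs[0] = 1.0
    for k in range(1, hets.size):
        h = hets[k - 1]
        hom_min = (n_minor - h) // 2
        hom_maj = (n_major - h) // 2
        probs[k] = probs[k - 1] * 4.0 * hom_min * hom_maj / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_individuals_removed: int = 0
    n_snps_call_rate: int = 0
    n_snps_hwe: int = 0
    n_snps_maf: int = 0
    n_snps_non_autosomal: int = 0
    removed_individuals: list = field(default_factory=list)

    @property
    def n_snps_removed(self) -> int:
        return (
            self.n_snps_call_rate + self.n_snps_hwe + self.n_snps_maf + self.n_snps_non_autosomal
        )


def _is_autosome(label: str, cfg: QCConfig) -> bool:
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() not in cfg.non_autosomes


def apply_qc(vt: VariantTable, hm: np.ndarray, pm: PopulationMap, individual_ids,
             cfg: QCConfig | None = None):
    """Filter individuals and SNPs; returns ``(vt, hm, individual_ids, QCReport)``.

    Individuals below the call-rate floor are removed first; SNP filters
    then run in the order call rate, per-breed HWE (a SNP failing in any
    one breed is removed globally), minor allele frequency, autosome-only.
    """
    if cfg is None:
        cfg = QCConfig()
    report = QCReport()
    missing = hm < 0
    n_ind = len(individual_ids)

    # (i) individual call rate
    ind_missing = missing.reshape(n_ind, 2, -1).any(axis=1)  # either haplotype missing
    call_rate = 1.0 - ind_missing.mean(axis=1)
    keep_ind = call_rate > cfg.min_individual_call_rate
    report.removed_individuals = [i for i, k in zip(individual_ids, keep_ind) if not k]
    report.n_individuals_removed = int((~keep_ind).sum())
    if report.n_individuals_removed:
        rows = np.repeat(keep_ind, 2)
        hm = hm[rows]
        individual_ids = [i for i, k in zip(individual_ids, keep_ind) if k]
        missing = hm < 0
        n_ind = len(individual_ids)

    keep = np.ones(len(vt), dtype=bool)

    # (ii) SNP call rate
    ind_missing = missing.reshape(n_ind, 2, -1).any(axis=1)
    snp_call = 1.0 - ind_missing.mean(axis=0)
    fail = snp_call <= cfg.min_snp_call_rate
    report.n_snps_call_rate = int((fail & keep).sum())
    keep &= ~fail

    # (iii) HWE exact test per breed
    hwe_fail = np.zeros(len(vt), dtype=bool)
    for pool in pm.pools:
        rows = pm.haplotype_rows(pool, individual_ids)
        if rows.size == 0:
            continue
        sub = hm[rows].reshape(rows.size // 2, 2, -1)
        ok = ~(sub < 0).any(axis=1)  # individuals with complete genotype per site
        g = sub.sum(axis=1)  # 0/1/2 derived copies
        for j in np.flatnonzero(keep):
            gj = g[ok[:, j], j]
            if gj.size == 0:
                continue
            n_het = int((gj == 1).sum())
            n_hom1 = int((gj == 2).sum())
            n_hom0 = int((gj == 0).sum())
            if hwe_exact_p(n_het, n_hom1, n_hom0) <= cfg.hwe_p_min:
                hwe_fail[j] = True
    report.n_snps_hwe = int((hwe_fail & keep).sum())
    keep &= ~hwe_fail

    # (iv) minor allele frequency over all retained individuals
    valid = hm >= 0
    alt = np.where(valid, hm, 0).sum(axis=0)
    tot = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    fail = maf <= cfg.maf_min
    report.n_snps_maf = int((fail & keep).sum())
    keep &= ~fail

    # (v) autosomes only
    if cfg.autosomes_only:
        fail = np.array([not _is_autosome(c, cfg) for c in vt.chrom])
        report.n_snps_non_autosomal = int((fail & keep).sum())
        keep &= ~fail

    if not keep.any():
        raise ValueError("QC removed every SNP")
    return vt.subset(keep), hm[:, keep], individual_ids, report


def fill_missing(hm: np.ndarray, pm: PopulationMap, individual_ids) -> np.ndarray:
    """Replace residual missing calls with the per-pool major allele (logged)."""
    hm = hm.copy()
    n_filled = 0
    for pool in pm.pools:
        rows = pm.haplotype_rows(pool, individual_ids)
        sub = hm[rows]
        miss = sub < 0
        if not miss.any():
            continue
        valid = sub >= 0
        ones = np.where(valid, sub, 0).sum(axis=0)
        tot = valid.sum(axis=0)
        major = (ones * 2 > tot).astype(np.int8)  # ties fill with 0
        fill = np.broadcast_to(major, sub.shape)
        sub[miss] = fill[miss]
        hm[rows] = sub
        n_filled += int(miss.sum())
    if n_filled:
        log.info("filled %d missing haplotype calls with pool major alleles", n_filled)
    return hm


# ---------------------------------------------------------------------------
# ancestral coding and pooling
# ---------------------------------------------------------------------------

def derive_ancestral_coding(vt: VariantTable, hm: np.ndarray, pm: PopulationMap,
                            individual_ids):
    """Set the ancestral allele to the reference-pool major allele and recode.

    The wild reference pool proxies the ancestral population, so its major
    allele at each site is declared ancestral; exact 0.5/0.5 ties keep the
    current 0 allele.  The returned matrix codes ``1`` as derived; applying
    the operation twice is a no-op.
    """
    rows = pm.haplotype_rows(pm.reference_pool, individual_ids)
    if rows.size == 0:
        raise ValueError("reference pool has no individuals")
    sub = hm[rows]
    if (sub < 0).any():
        raise ValueError("missing calls in reference pool; run QC/fill first")
    freq1 = sub.mean(axis=0)
    flip = freq1 > 0.5  # current 1-allele is the reference major -> becomes ancestral
    new_hm = hm.copy()
    new_hm[:, flip] = np.where(new_hm[:, flip] >= 0, 1 - new_hm[:, flip], -1)
    new_vt = vt.copy()
    new_vt.ancestral_is_allele0 = np.where(flip, ~vt.ancestral_is_allele0,
                                           vt.ancestral_is_allele0)
    return new_vt, new_hm


def pool_haplotypes(hm: np.ndarray, pm: PopulationMap, pool, individual_ids) -> np.ndarray:
    """Submatrix of the haplotypes of one pool (or several), original order kept."""
    if isinstance(pool, str):
        rows = pm.haplotype_rows(pool, individual_ids)
    else:
        members = set(pool)
        for p in members:
            if p not in set(pm.pool_of.values()):
                raise KeyError(f"unknown pool label {p!r}")
        ind = np.array(
            [i for i, s in enumerate(individual_ids) if pm.pool_of.get(s) in members],
            dtype=np.int64,
        )
        rows = np.column_stack([2 * ind, 2 * ind + 1]).reshape(-1)
    return hm[rows]
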