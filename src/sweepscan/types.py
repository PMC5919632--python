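"""Core containers shared by every stage of the scan.

Conventions
-----------
* Variant positions are 1-based (VCF style) in :class:`VariantTable`;
  all interval arithmetic elsewhere uses 0-based half-open coordinates.
* A haplotype matrix is a plain ``numpy`` ``int8`` array of shape
  ``(2 * n_individuals, n_sites)``.  Rows ``2i`` and ``2i + 1`` are the two
  phased haplotypes of individual ``i``.  After ancestral coding, ``0`` is
  the ancestral and ``1`` the derived allele; ``-1`` marks a missing call
  and may only appear before QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VariantTable",
    "PopulationMap",
    "QCConfig",
    "window_index",
    "window_bounds",
]


@dataclass
class VariantTable:
    """Ordered biallelic SNP records aligned to the columns of a haplotype matrix.

    Attributes
    ----------
    chrom : array of str
        Chromosome label per site.
    pos : array of int
        1-based physical position, strictly increasing within a chromosome.
    snp_id : array of str
    allele0, allele1 : array of str
        The two observed alleles (nucleotide strings).
    ancestral_is_allele0 : array of bool
        Which allele the 0 code of the matrix refers to.  ``True`` until
        :func:`sweepscan.genotype_io.derive_ancestral_coding` decides otherwise.
    """

    chrom: np.ndarray
    pos: np.ndarray
    snp_id: np.ndarray
    allele0: np.ndarray
    allele1: np.ndarray
    ancestral_is_allele0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.allele0 = np.asarray(self.allele0, dtype=object)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        if self.ancestral_is_allele0 is None:
            self.ancestral_is_allele0 = np.ones(len(self.pos), dtype=bool)
        else:
            self.ancestral_is_allele0 = np.asarray(self.ancestral_is_allele0, dtype=bool)

    def __len__(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        """Raise ``ValueError`` if positions are not strictly increasing per chromosome."""
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous column slice of one chromosome (sites are chromosome-sorted)."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in table")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, mask_or_index) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[mask_or_index],
            pos=self.pos[mask_or_index],
            snp_id=self.snp_id[mask_or_index],
            allele0=self.allele0[mask_or_index],
            allele1=self.allele1[mask_or_index],
            ancestral_is_allele0=self.ancestral_is_allele0[mask_or_index],
        )

    def copy(self) -> "VariantTable":
        return replace(
            self,
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            snp_id=self.snp_id.copy(),
            allele0=self.allele0.copy(),
            allele1=self.allele1.copy(),
            ancestral_is_allele0=self.ancestral_is_allele0.copy(),
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.pos == other.pos))
            and bool(np.all(self.snp_id == other.snp_id))
            and bool(np.all(self.allele0 == other.allele0))
            and bool(np.all(self.allele1 == other.allele1))
            and bool(np.all(self.ancestral_is_allele0 == other.ancestral_is_allele0))
        )


@dataclass
class PopulationMap:
    """Assignment of individuals to pools, with one pool flagged as the wild reference."""

    pool_of: dict
    reference_pool: str

    def __post_init__(self) -> None:
        if self.reference_pool not in set(self.pool_of.values()):
            raise ValueError(f"reference pool {self.reference_pool!r} has no individuals")

    @property
    def pools(self) -> list:
        seen: dict = {}
        for p in self.pool_of.values():
            seen.setdefault(p, None)
        return list(seen)

    def domestic_pools(self) -> list:
        return [p for p in self.pools if p != self.reference_pool]

    def individuals_in(self, pool: str, individual_ids) -> np.ndarray:
        """Indices (into *individual_ids*) of the members of *pool*, input order kept."""
        if pool not in set(self.pool_of.values()):
            raise KeyError(f"unknown pool label {pool!r}")
        return np.array(
            [i for i, ind in enumerate(individual_ids) if self.pool_of.get(ind) == pool],
            dtype=np.int64,
        )

    def haplotype_rows(self, pool: str, individual_ids) -> np.ndarray:
        """Haplotype-row indices (2 per individual) of the members of *pool*."""
        ind = self.individuals_in(pool, individual_ids)
        return np.column_stack([2 * ind, 2 * ind + 1]).reshape(-1)

    def subset(self, individual_ids) -> "PopulationMap":
        keep = {i: self.pool_of[i] for i in individual_ids if i in self.pool_of}
        return PopulationMap(pool_of=keep, reference_pool=self.reference_pool)


@dataclass
class QCConfig:
    """Thresholds of the marker/individual quality filters.

    Defaults follow common SNP-array practice: individuals below 95%
    call rate are removed first, then SNPs are filtered on call rate,
    per-breed Hardy-Weinberg exact-test p, minor allele frequency, and
    an autosome-only rule.
    """

    min_individual_call_rate: float = 0.95
    min_snp_call_rate: float = 0.99
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    autosomes_only: bool = True
    #: chromosome labels never treated as autosomes (case-insensitive,
    #: with or without a "chr" prefix)
    non_autosomes: tuple = ("X", "Y", "Z", "W", "M", "MT", "UN")

    def __post_init__(self) -> None:
        for name in ("min_individual_call_rate", "min_snp_call_rate", "hwe_p_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def window_index(pos: np.ndarray, width: int = 10_000) -> np.ndarray:
    """Index of the fixed-width window containing each 1-based position.

    Windows tile each chromosome from position 1, so position ``width``
    still belongs to window 0.
    """
    return (np.asarray(pos, dtype=np.int64) - 1) // width


def window_bounds(index: np.ndarray, width: int = 10_000) -> tuple:
    """0-based half-open (start, end) of each window index."""
    index = np.asarray(index, dtype=np.int64)
    return index * width, (index + 1) * width
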