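"""genotype_io: parsing, QC filters, ancestral coding and pooling."""

import numpy as np
import pytest

from sweepscan import genotype_io as gio
from sweepscan.types import PopulationMap, QCConfig, VariantTable
from tests.conftest import make_vt

VCF_BODY = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tindA\tindB
1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1
1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0|0\t0|1
1\t300\trs3\tG\tA\t.\t.\t.\tGT\t1|0\t0|0
"""


def write(tmp_path, text, name="toy.vcf"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadVcf:
    def test_direct_transcription(self, tmp_path):
        vt, hm, ids = gio.read_genotypes(write(tmp_path, VCF_BODY), "vcf")
        assert ids == ["indA", "indB"]
        assert hm.shape == (4, 3)
        # rows are (indA.hapA, indA.hapB, indB.hapA, indB.hapB)
        assert hm.tolist() == [[0, 0, 1], [1, 0, 0], [1, 0, 0], [1, 1, 0]]
        assert list(vt.pos) == [100, 200, 300]
        assert list(vt.allele0) == ["A", "C", "G"]

    def test_triallelic_record_dropped(self, tmp_path, caplog):
        body = VCF_BODY.replace("1\t200\trs2\tC\tT", "1\t200\trs2\tC\tT,G")
        # a triallelic GT index of 2 would confuse transcription; keep 0/1 codes
        body = body.replace("0|0\t0|1", "0|0\t0|1")
        vt, hm, ids = gio.read_genotypes(write(tmp_path, body), "vcf")
        assert len(vt) == 2
        assert list(vt.pos) == [100, 300]

    def test_unphased_heterozygote_rejected(self, tmp_path):
        body = VCF_BODY.replace("0|1\t1|1", "0/1\t1|1")
        with pytest.raises(ValueError, match="unphased"):
            gio.read_genotypes(write(tmp_path, body), "vcf")

    def test_vcf_round_trip(self, tmp_path, small_sim):
        vt, hm, pm, ids, _ = small_sim
        out = tmp_path / "rt.vcf"
        gio.write_vcf(out, vt, hm, ids)
        vt2, hm2, ids2 = gio.read_genotypes(out, "vcf")
        assert ids2 == list(ids)
        assert vt.equals(vt2)
        assert np.array_equal(hm, hm2)


class TestPlinkText:
    def test_round_trip_matches_vcf_content(self, tmp_path):
        vt, hm, ids = gio.read_genotypes(write(tmp_path, VCF_BODY), "vcf")
        ped = tmp_path / "toy.ped"
        mp = tmp_path / "toy.map"
        mp.write_text("".join(
            f"{vt.chrom[j]} {vt.snp_id[j]} 0 {vt.pos[j]}\n" for j in range(len(vt))
        ))
        with open(ped, "w") as fh:
            for i, ind in enumerate(ids):
                alleles = []
                for j in range(len(vt)):
                    for k in (0, 1):
                        code = hm[2 * i + k, j]
                        alleles.append(vt.allele0[j] if code == 0 else vt.allele1[j])
                fh.write(f"FAM {ind} 0 0 0 -9 " + " ".join(alleles) + "\n")
        vt2, hm2, ids2 = gio.read_genotypes(ped, "plink-text")
        assert ids2 == ids
        assert list(vt2.pos) == list(vt.pos)
        # allele0/1 assignment is first-seen in ped text; compare genotype content
        for j in range(len(vt)):
            a = [vt.allele0[j] if c == 0 else vt.allele1[j] for c in hm[:, j]]
            b = [vt2.allele0[j] if c == 0 else vt2.allele1[j] for c in hm2[:, j]]
            assert a == b


class TestHweExact:
    def brute_force(self, n_het, n_hom_min, n_hom_maj):
        """Enumerate all genotype tables with these allele counts."""
        from math import comb

        n = n_het + n_hom_min + n_hom_maj
        na = 2 * n_hom_min + n_het
        probs = {}
        for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
            hom_min = (na - h) // 2
            hom_maj = n - h - hom_min
            if hom_min < 0 or hom_maj < 0:
                continue
            # P(h) proportional to n! / (hom_min! h! hom_maj!) * 2^h
            w = comb(n, h) * comb(n - h, hom_min) * 2 ** h
            probs[h] = w
        tot = sum(probs.values())
        p_obs = probs[n_het] / tot
        return sum(p / tot for p in probs.values() if p / tot <= p_obs * (1 + 1e-12))

    @pytest.mark.parametrize("het,hom_min,hom_maj", [
        (2, 3, 5), (0, 5, 5), (10, 0, 0), (1, 1, 8), (4, 0, 16), (7, 2, 2),
    ])
    def test_matches_exhaustive_enumeration(self, het, hom_min, hom_maj):
        assert gio.hwe_exact_p(het, hom_min, hom_maj) == pytest.approx(
            self.brute_force(het, hom_min, hom_maj), rel=1e-10)

    def test_extreme_deficit_is_tiny(self):
        # 24 individuals, no heterozygotes, alleles at 50/50: far off equilibrium
        assert gio.hwe_exact_p(0, 12, 12) < 1e-6


class TestApplyQc:
    def _pm(self, ids):
        half = len(ids) // 2
        pool_of = {i: ("A" if k < half else "B") for k, i in enumerate(ids)}
        return PopulationMap(pool_of=pool_of, reference_pool="A")

    def test_low_maf_snp_removed(self):
        rng = np.random.default_rng(0)
        ids = [f"i{k}" for k in range(100)]
        hm = rng.integers(0, 2, size=(200, 3)).astype(np.int8)
        hm[:, 1] = 0
        hm[0, 1] = 1  # MAF 1/200 = 0.005 <= 0.01
        vt = make_vt([100, 200, 300])
        vt2, hm2, ids2, rep = gio.apply_qc(vt, hm, self._pm(ids), ids)
        assert list(vt2.pos) == [100, 300]
        assert rep.n_snps_maf == 1

    def test_monomorphic_snp_removed_by_maf_rule(self):
        ids = [f"i{k}" for k in range(20)]
        rng = np.random.default_rng(1)
        hm = rng.integers(0, 2, size=(40, 2)).astype(np.int8)
        hm[:, 0] = 1
        vt = make_vt([10, 20])
        vt2, _, _, rep = gio.apply_qc(vt, hm, self._pm(ids), ids)
        assert list(vt2.pos) == [20]
        assert rep.n_snps_maf == 1

    def test_hwe_failure_in_one_breed_removes_globally(self):
        # breed A: 24 individuals with no heterozygotes at 50/50 alleles
        # (exact p < 1e-6); breed B in perfect equilibrium
        ids = [f"a{k}" for k in range(24)] + [f"b{k}" for k in range(24)]
        pm = PopulationMap(pool_of={**{f"a{k}": "A" for k in range(24)},
                                    **{f"b{k}": "B" for k in range(24)}},
                           reference_pool="A")

        def genotypes(n_hom0, n_het, n_hom1):
            g = [(0, 0)] * n_hom0 + [(0, 1)] * n_het + [(1, 1)] * n_hom1
            return np.array(g, dtype=np.int8).reshape(-1)

        hw_ok = genotypes(6, 12, 6)  # exact Hardy-Weinberg proportions
        hm = np.zeros((96, 2), dtype=np.int8)
        hm[:48, 0] = genotypes(12, 0, 12)  # breed A: total het deficit
        hm[48:, 0] = hw_ok
        hm[:48, 1] = hw_ok  # site 1 in equilibrium in both breeds
        hm[48:, 1] = hw_ok
        assert gio.hwe_exact_p(0, 12, 12) < 1e-6
        assert gio.hwe_exact_p(12, 6, 6) > 1e-6
        vt = make_vt([10, 20])
        vt2, _, _, rep = gio.apply_qc(vt, hm, pm, ids)
        assert rep.n_snps_hwe == 1
        assert list(vt2.pos) == [20]

    def test_non_autosomal_removed_and_individual_call_rate(self):
        ids = [f"i{k}" for k in range(10)]
        rng = np.random.default_rng(3)
        hm = rng.integers(0, 2, size=(20, 4)).astype(np.int8)
        hm[0, :] = -1  # i0 misses every site -> call rate 0
        vt = VariantTable(chrom=["1", "1", "Z", "chrW"], pos=[10, 20, 30, 40],
                          snp_id=list("abcd"), allele0=["A"] * 4, allele1=["G"] * 4)
        vt2, hm2, ids2, rep = gio.apply_qc(vt, hm, self._pm(ids), ids)
        assert rep.n_individuals_removed == 1
        assert "i0" not in ids2
        assert rep.n_snps_non_autosomal == 2
        assert all(c == "1" for c in vt2.chrom)

    def test_qc_is_idempotent(self, small_sim):
        vt, hm, pm, ids, _ = small_sim
        vt1, hm1, ids1, _ = gio.apply_qc(vt, hm, pm, ids)
        vt2, hm2, ids2, rep2 = gio.apply_qc(vt1, hm1, pm, ids1)
        assert vt1.equals(vt2)
        assert np.array_equal(hm1, hm2)
        assert rep2.n_snps_removed == 0 and rep2.n_individuals_removed == 0

    def test_all_snps_removed_is_an_error(self):
        ids = ["i0", "i1", "i2", "i3"]
        hm = np.zeros((8, 2), dtype=np.int8)  # everything monomorphic
        vt = make_vt([10, 20])
        with pytest.raises(ValueError, match="every SNP"):
            gio.apply_qc(vt, hm, self._pm(ids), ids)


class TestAncestralCoding:
    def _setup(self, ref_col):
        ids = ["w1", "w2", "d1", "d2"]
        pm = PopulationMap(pool_of={"w1": "W", "w2": "W", "d1": "D", "d2": "D"},
                           reference_pool="W")
        hm = np.zeros((8, 1), dtype=np.int8)
        hm[:4, 0] = ref_col
        hm[4:, 0] = [1, 1, 0, 1]
        return make_vt([100]), hm, pm, ids

    def test_reference_major_becomes_ancestral(self):
        vt, hm, pm, ids = self._setup([1, 1, 1, 0])  # allele1 is ref major
        vt2, hm2 = gio.derive_ancestral_coding(vt, hm, pm, ids)
        assert not vt2.ancestral_is_allele0[0]
        # matrix recoded: ref-pool derived (now allele0) frequency 1/4
        assert hm2[:4, 0].mean() == 0.25

    def test_exact_tie_keeps_allele0(self):
        vt, hm, pm, ids = self._setup([0, 0, 1, 1])
        vt2, hm2 = gio.derive_ancestral_coding(vt, hm, pm, ids)
        assert vt2.ancestral_is_allele0[0]
        assert np.array_equal(hm, hm2)

    def test_idempotent(self, small_sim):
        vt, hm, pm, ids, _ = small_sim
        vt1, hm1 = gio.derive_ancestral_coding(vt, hm, pm, ids)
        vt2, hm2 = gio.derive_ancestral_coding(vt1, hm1, pm, ids)
        assert np.array_equal(vt1.ancestral_is_allele0, vt2.ancestral_is_allele0)
        assert np.array_equal(hm1, hm2)

    def test_reference_derived_frequency_at_most_half(self, small_sim):
        vt, hm, pm, ids, _ = small_sim
        vt1, hm1 = gio.derive_ancestral_coding(vt, hm, pm, ids)
        ref = gio.pool_haplotypes(hm1, pm, pm.reference_pool, ids)
        assert (ref.mean(axis=0) <= 0.5 + 1e-12).all()


class TestPoolHaplotypes:
    def test_single_individual_pool(self, tiny_vt):
        pm = PopulationMap(pool_of={"a": "X", "b": "Y", "c": "Y"},
                           reference_pool="X")
        hm = np.arange(30, dtype=np.int8).reshape(6, 5)
        sub = gio.pool_haplotypes(hm, pm, "X", ["a", "b", "c"])
        assert sub.shape == (2, 5)
        assert np.array_equal(sub, hm[:2])

    def test_union_of_pools_restores_all_rows(self, small_sim):
        vt, hm, pm, ids, _ = small_sim
        rows = np.vstack([gio.pool_haplotypes(hm, pm, p, ids) for p in pm.pools])
        assert sorted(map(tuple, rows)) == sorted(map(tuple, hm))

    def test_two_labels_equal_concatenation(self, small_sim):
        vt, hm, pm, ids, _ = small_sim
        both = gio.pool_haplotypes(hm, pm, pm.pools, ids)
        parts = np.vstack([gio.pool_haplotypes(hm, pm, p, ids) for p in pm.pools])
        assert sorted(map(tuple, both)) == sorted(map(tuple, parts))

    def test_unknown_pool_label(self, small_sim):
        vt, hm, pm, ids, _ = small_sim
        with pytest.raises(KeyError):
            gio.pool_haplotypes(hm, pm, "NOPE", ids)
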