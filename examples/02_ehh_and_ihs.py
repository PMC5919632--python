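"""EHH curves and unstandardized iHS at single SNPs.

Simulates one neutral pool, picks a mid-frequency core SNP, and prints the
extended haplotype homozygosity decay for both alleles together with the
integrated areas and the iHS score.
"""

import numpy as np

from sweepscan import genotype_io, ihs
from sweepscan.simulate import SimConfig, simulate

vt, hm, pm, ids, _ = simulate(SimConfig(seed=3, n_sites=1200,
                                        chrom_length=1_500_000,
                                        t_burnin=200, t_split=20))
vt, hm = genotype_io.derive_ancestral_coding(vt, hm, pm, ids)
pool = genotype_io.pool_haplotypes(hm, pm, "DOM1", ids)

freq = pool.mean(axis=0)
core = int(np.argmin(np.abs(freq - 0.5)))  # a balanced core SNP
print(f"core SNP at {vt.pos[core]:,} bp, derived frequency {freq[core]:.2f}")

for allele, label in ((0, "ancestral"), (1, "derived")):
    prof = ihs.ehh_curve(pool, vt, core, allele)
    span = prof.positions[-1] - prof.positions[0]
    print(f"  {label}: EHH tracked over {span:,} bp, "
          f"{len(prof.ehh)} markers, min EHH {prof.ehh.min():.3f}")

ihh_a, ihh_d, score = ihs.ihs_site(pool, vt, core)
print(f"iHH_A = {ihh_a:,.0f} bp, iHH_D = {ihh_d:,.0f} bp, "
      f"unstandardized iHS = ln(iHH_A/iHH_D) = {score:+.3f}")
# A positive iHS means longer haplotypes around the ancestral allele; at a
# neutral balanced SNP the score hovers near zero.

track = ihs.window_abs_ihs(ihs.ihs_scan(pool, vt))
print(f"windowed |iHS|: {len(track)} non-empty 10 kb windows, "
      f"genome mean {track['value'].mean():.3f}")
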