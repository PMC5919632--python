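"""Forward-in-time Wright-Fisher simulator with injected hard and soft sweeps.

The generator emulates the study design the scan assumes: several diploid
pools descended from one ancestral population, the first pool being an
unselected wild reference, dense biallelic SNPs with realistic linkage
disequilibrium, and beneficial alleles driven toward fixation in the
domestic pools only.

Model
-----
Discrete generations, diploid Wright-Fisher, random mating.  Candidate SNP
sites sit on a fixed lattice of positions on one chromosome; gametes
recombine with crossovers placed uniformly (Poisson number with mean
``rec_rate * chrom_length``) and sites mutate recurrently between their two
alleles at a small rate ``mu``.  Standing variation is initialised with
Beta(``init_beta``, ``init_beta``) site frequencies truncated at the
panel-design MAF floor (a SNP array targets variants common at design
time), and a burn-in of a few hundred generations builds linkage
disequilibrium before the split.

At the split each pool founds from a disjoint sample of the ancestral
diploids (identical copies only in the ``n_per_pool == n_ancestral``
limit); thereafter pools evolve independently with no migration.  The wild
population persists at the larger ``n_wild`` and the reference pool is a
sample of it taken at output.  Selection is genic (fitness 1, 1+s, 1+2s)
and applies only in the domestic pool each sweep targets.  A hard sweep
introduces a brand-new allele on a single haplotype of the selected pool
(the site is zeroed everywhere first, so the reference frequency is 0 by
construction); a soft sweep selects a pre-existing variant whose ancestral
frequency at the split lies within +/-0.05 of the requested ``f0``.

Like a SNP array, the emitted data keep only sites with combined-sample
MAF > 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .types import PopulationMap, VariantTable
from . import genotype_io

log = logging.getLogger(__name__)

__all__ = ["SweepSpec", "SimConfig", "SweepTruth", "simulate", "emit"]

_NUCS = np.array(list("ACGT"), dtype=object)


@dataclass(frozen=True)
class SweepSpec:
    """One injected sweep: lattice-snapped position, type, selection coefficient.

    ``pool`` names the domestic pool under selection for this sweep; when
    ``None`` the first domestic pool is selected.  Other pools (and always
    the reference) evolve neutrally at this locus.
    """

    position: int
    kind: str  # "hard" | "soft"
    s: float = 0.3  # breed improvement is strong, recent selection
    f0: float = 0.25  # standing frequency at the split (soft sweeps only)
    pool: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("hard", "soft"):
            raise ValueError(f"sweep kind must be 'hard' or 'soft', got {self.kind!r}")
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.kind == "soft" and not 0.0 < self.f0 < 1.0:
            raise ValueError("soft-sweep f0 must lie in (0, 1)")


@dataclass
class SimConfig:
    """Simulation parameters; the seed fully determines the output."""

    n_ancestral: int = 100
    n_per_pool: int = 50
    n_pools: int = 2  # first pool is the unselected wild reference
    n_sites: int = 15000
    chrom_length: int = 10_000_000  # total, split evenly over n_chroms
    #: number of chromosomes, simulated as independent genealogies of the
    #: same individuals (deep coalescent histories of unlinked chromosomes
    #: are effectively independent); sweeps are placed on chromosome "1"
    n_chroms: int = 1
    mu: float = 1e-5
    rec_rate: float = 1e-7
    #: symmetric Beta shape of the initial site-frequency distribution;
    #: stands in for the ascertained standing variation of a SNP panel
    init_beta: float = 0.2
    #: panel-design ascertainment: initial site MAF floor (arrays target
    #: variants that were common when the chip was designed)
    init_maf_min: float = 0.05
    #: wild population size after the split (the reference pool is a sample
    #: of a large, unselected population); defaults to 5 x n_ancestral
    n_wild: int | None = None
    t_burnin: int = 300
    t_split: int = 50
    sweeps: list = field(default_factory=list)
    maf_ascertainment: float = 0.01
    max_restarts: int = 50
    seed: int = 0
    chrom: str = "1"
    reference_label: str = "WILD"
    pool_prefix: str = "DOM"

    def pool_labels(self) -> list:
        return [self.reference_label] + [
            f"{self.pool_prefix}{k}" for k in range(1, self.n_pools)
        ]


@dataclass
class SweepTruth:
    """Ground truth for one injected sweep after the run."""

    pool: str  # the selected pool
    position: int
    kind: str
    s: float
    f0: float
    site_index: int  # column in the emitted VariantTable, -1 if ascertained away
    final_freq: dict  # pool label -> beneficial-allele frequency


# ---------------------------------------------------------------------------
# core Wright-Fisher machinery
# ---------------------------------------------------------------------------

def _gametes(pop: np.ndarray, parents: np.ndarray, positions: np.ndarray,
             rec_lambda: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent in *parents* (diploid indices into *pop*)."""
    n = parents.size
    S = pop.shape[1]
    out = np.empty((n, S), dtype=np.int8)
    n_cross = rng.poisson(rec_lambda, size=n)
    start = rng.integers(0, 2, size=n)
    plain = n_cross == 0
    out[plain] = pop[2 * parents[plain] + start[plain]]
    for i in np.flatnonzero(~plain):
        cuts = np.sort(rng.uniform(0, positions[-1] + 1, size=n_cross[i]))
        phase = (np.searchsorted(cuts, positions) + start[i]) % 2
        h0 = pop[2 * parents[i]]
        h1 = pop[2 * parents[i] + 1]
        out[i] = np.where(phase == 0, h0, h1)
    return out


def _mutate(pop: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    n_mut = rng.poisson(mu * pop.size)
    if n_mut == 0:
        return
    rows = rng.integers(0, pop.shape[0], size=n_mut)
    cols = rng.integers(0, pop.shape[1], size=n_mut)
    pop[rows, cols] = 1 - pop[rows, cols]


def _next_generation(pop: np.ndarray, n_offspring: int, positions: np.ndarray,
                     rec_lambda: float, mu: float, rng: np.random.Generator,
                     fitness: np.ndarray | None = None) -> np.ndarray:
    n_parents = pop.shape[0] // 2
    if fitness is None:
        mothers = rng.integers(0, n_parents, size=n_offspring)
        fathers = rng.integers(0, n_parents, size=n_offspring)
    else:
        w = fitness / fitness.sum()
        mothers = rng.choice(n_parents, size=n_offspring, p=w)
        fathers = rng.choice(n_parents, size=n_offspring, p=w)
    g0 = _gametes(pop, mothers, positions, rec_lambda, rng)
    g1 = _gametes(pop, fathers, positions, rec_lambda, rng)
    nxt = np.empty((2 * n_offspring, pop.shape[1]), dtype=np.int8)
    nxt[0::2] = g0
    nxt[1::2] = g1
    _mutate(nxt, mu, rng)
    return nxt


def _fitness(pop: np.ndarray, sweep_sites: list) -> np.ndarray | None:
    """Multiplicative genic fitness over the sweep sites, per diploid."""
    if not sweep_sites:
        return None
    n = pop.shape[0] // 2
    w = np.ones(n, dtype=float)
    for j, s in sweep_sites:
        g = pop[0::2, j].astype(float) + pop[1::2, j]
        w *= 1.0 + s * g
    return w


# ---------------------------------------------------------------------------
# sweep placement
# ---------------------------------------------------------------------------

def _snap_hard(anc: np.ndarray, positions: np.ndarray, want: int) -> int:
    return int(np.argmin(np.abs(positions - want)))


def _snap_soft(anc: np.ndarray, positions: np.ndarray, want: int, f0: float,
               tol: float = 0.05) -> int:
    freq = anc.mean(axis=0)
    ok = np.abs(freq - f0) <= tol
    if not ok.any():
        raise RuntimeError(
            f"no standing variant with frequency within {tol} of {f0}; "
            "increase n_sites or the burn-in"
        )
    cand = np.flatnonzero(ok)
    return int(cand[np.argmin(np.abs(positions[cand] - want))])


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig):
    """Run the simulation; returns ``(vt, hm, pm, individual_ids, truths)``.

    Output is phased, QC-clean by construction (no missing calls, array-like
    MAF ascertainment), with haplotypes coded 0 = ancestral / 1 = derived
    relative to the simulated ancestral state.  With ``n_chroms > 1`` each
    chromosome is an independent Wright-Fisher realization of the same
    pooled individuals; injected sweeps land on chromosome "1".
    """
    if cfg.n_chroms > 1:
        return _simulate_multi(cfg)
    rng = np.random.default_rng(cfg.seed)
    positions = np.sort(rng.choice(np.arange(1, cfg.chrom_length + 1),
                                   size=cfg.n_sites, replace=False))
    rec_lambda = cfg.rec_rate * cfg.chrom_length

    # standing variation with a U-shaped frequency spectrum truncated at the
    # panel-design MAF floor, then a burn-in that builds linkage
    # disequilibrium (and loses some rare variants to drift)
    freq0 = np.empty(cfg.n_sites)
    todo = np.arange(cfg.n_sites)
    while todo.size:
        draw = rng.beta(cfg.init_beta, cfg.init_beta, size=todo.size)
        ok = np.minimum(draw, 1.0 - draw) > cfg.init_maf_min
        freq0[todo[ok]] = draw[ok]
        todo = todo[~ok]
    pop = (rng.random((2 * cfg.n_ancestral, cfg.n_sites)) < freq0).astype(np.int8)
    for _ in range(cfg.t_burnin):
        pop = _next_generation(pop, cfg.n_ancestral, positions, rec_lambda, cfg.mu, rng)

    # split samples: disjoint draws from the ancestral population when they
    # fit, otherwise independent without-replacement draws per pool (so that
    # n_per_pool == n_ancestral makes every pool an identical copy)
    npp, npools = cfg.n_per_pool, cfg.n_pools
    if npools * npp <= cfg.n_ancestral:
        perm = rng.permutation(cfg.n_ancestral)
        picks = [np.sort(perm[k * npp:(k + 1) * npp]) for k in range(npools)]
    else:
        picks = [np.sort(rng.choice(cfg.n_ancestral, size=npp, replace=False))
                 for _ in range(npools)]
    splits = [pop[np.column_stack([2 * p, 2 * p + 1]).reshape(-1)].copy()
              for p in picks]

    sweeps = [s if isinstance(s, SweepSpec) else SweepSpec(*s) for s in cfg.sweeps]
    sweep_sites: list = []
    for sw in sweeps:
        if sw.kind == "hard":
            j = _snap_hard(pop, positions, sw.position)
            pop[:, j] = 0  # de novo: absent everywhere at the split
            for split in splits:
                split[:, j] = 0
        else:
            j = _snap_soft(pop, positions, sw.position, sw.f0)
        sweep_sites.append((j, sw.s))

    labels = cfg.pool_labels()
    default_pool = labels[1] if len(labels) > 1 else None
    target_of = [sw.pool if sw.pool is not None else default_pool for sw in sweeps]
    for t in target_of:
        if t not in labels or t == cfg.reference_label:
            raise ValueError(f"sweep targets unknown or reference pool {t!r}")
    pools = {}
    for k, label in enumerate(labels):
        selected = k > 0
        my_sites = [site for site, tgt in zip(sweep_sites, target_of) if tgt == label]
        my_sweeps = [sw for sw, tgt in zip(sweeps, target_of) if tgt == label]
        prng = np.random.default_rng((cfg.seed, 1 + k))
        for attempt in range(cfg.max_restarts + 1):
            if not selected:
                # the wild population persists at the ancestral size; the
                # reference pool is a sample of it taken at the end
                if cfg.t_split == 0:
                    pools[label] = splits[0].copy()
                    break
                n_wild = cfg.n_wild if cfg.n_wild is not None else 5 * cfg.n_ancestral
                n_wild = max(n_wild, cfg.n_per_pool)  # must fit the output sample
                cur = pop.copy()
                for g in range(cfg.t_split):
                    cur = _next_generation(cur, n_wild, positions,
                                           rec_lambda, cfg.mu, prng)
                sample = np.sort(prng.choice(cur.shape[0] // 2, size=cfg.n_per_pool,
                                             replace=False))
                rows = np.column_stack([2 * sample, 2 * sample + 1]).reshape(-1)
                pools[label] = cur[rows].copy()
                break
            cur = splits[k].copy()
            for (j, _s), sw in zip(my_sites, my_sweeps):
                if sw.kind == "hard":
                    cur[prng.integers(0, cur.shape[0]), j] = 1
            for _ in range(cfg.t_split):
                w = _fitness(cur, my_sites)
                cur = _next_generation(cur, cfg.n_per_pool, positions, rec_lambda,
                                       cfg.mu, prng, fitness=w)
            ok = True
            for (j, _s), sw in zip(my_sites, my_sweeps):
                if sw.s > 0 and cur[:, j].mean() == 0.0:
                    ok = False  # beneficial allele drifted out; retry this pool
            if ok:
                pools[label] = cur
                break
        else:
            raise RuntimeError(
                "beneficial allele lost in every attempt; increase s or max_restarts"
            )

    return _package(cfg, positions, pools, labels, sweeps, sweep_sites, target_of, rng)


def _package(cfg, positions, pools, labels, sweeps, sweep_sites, target_of, rng):
    hm = np.vstack([pools[label] for label in labels])
    individual_ids = []
    pool_of = {}
    for label in labels:
        for i in range(cfg.n_per_pool):
            ind = f"{label}_{i:03d}"
            individual_ids.append(ind)
            pool_of[ind] = label
    pm = PopulationMap(pool_of=pool_of, reference_pool=cfg.reference_label)

    # array-like ascertainment on the combined sample
    freq = hm.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > cfg.maf_ascertainment
    for j, _ in sweep_sites:
        keep[j] = keep[j] or maf[j] > 0  # never silently drop a polymorphic sweep site
    kept_index = {j: k for k, j in enumerate(np.flatnonzero(keep))}

    # deterministic distinct allele pair per site
    a0 = rng.integers(0, 4, size=cfg.n_sites)
    a1 = (a0 + rng.integers(1, 4, size=cfg.n_sites)) % 4
    alleles = np.column_stack([_NUCS[a0], _NUCS[a1]])

    kept = np.flatnonzero(keep)
    vt = VariantTable(
        chrom=[cfg.chrom] * kept.size,
        pos=positions[kept],
        snp_id=[f"snp{j}" for j in kept],
        allele0=alleles[kept, 0],
        allele1=alleles[kept, 1],
    )
    hm_out = hm[:, kept].copy()

    truths = []
    for (j, _s), sw, tgt in zip(sweep_sites, sweeps, target_of):
        final = {label: float(pools[label][:, j].mean()) for label in labels}
        truths.append(SweepTruth(
            pool=tgt, position=int(positions[j]), kind=sw.kind, s=sw.s,
            f0=sw.f0 if sw.kind == "soft" else 0.0,
            site_index=kept_index.get(j, -1), final_freq=final,
        ))
    return vt, hm_out, pm, individual_ids, truths


def _simulate_multi(cfg: SimConfig):
    """Concatenate independent single-chromosome runs over shared individuals."""
    from dataclasses import replace as _replace

    vts, hms = [], []
    truths: list = []
    pm = individual_ids = None
    for c in range(cfg.n_chroms):
        sub_seed = int(np.random.SeedSequence((cfg.seed, 7001 + c))
                       .generate_state(1)[0] % (2 ** 31))
        sub = _replace(cfg, n_chroms=1, seed=sub_seed, chrom=str(c + 1),
                       n_sites=cfg.n_sites // cfg.n_chroms,
                       chrom_length=cfg.chrom_length // cfg.n_chroms,
                       sweeps=cfg.sweeps if c == 0 else [])
        vt_c, hm_c, pm, individual_ids, truths_c = simulate(sub)
        vts.append(vt_c)
        hms.append(hm_c)
        if c == 0:
            offset = 0
            for t in truths_c:
                if t.site_index >= 0:
                    t.site_index += offset
            truths = truths_c
    vt = VariantTable(
        chrom=np.concatenate([v.chrom for v in vts]),
        pos=np.concatenate([v.pos for v in vts]),
        snp_id=np.concatenate([np.array([f"c{i + 1}_{s}" for s in v.snp_id],
                                        dtype=object)
                               for i, v in enumerate(vts)]),
        allele0=np.concatenate([v.allele0 for v in vts]),
        allele1=np.concatenate([v.allele1 for v in vts]),
        ancestral_is_allele0=np.concatenate([v.ancestral_is_allele0 for v in vts]),
    )
    return vt, np.hstack(hms), pm, individual_ids, truths


def emit(vt, hm, pm, individual_ids, truths, out_dir):
    """Write VCF, population map and truth TSV; returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf = out_dir / "genotypes.vcf"
    popmap = out_dir / "popmap.tsv"
    truth = out_dir / "truth.tsv"
    genotype_io.write_vcf(vcf, vt, hm, individual_ids)
    genotype_io.write_population_map(popmap, pm)
    with open(truth, "w") as fh:
        fh.write("pool\tposition\tkind\ts\tf0\tsite_index\t"
                 + "\t".join(f"freq_{p}" for p in pm.pools) + "\n")
        for t in truths:
            freqs = "\t".join(f"{t.final_freq[p]:.6f}" for p in pm.pools)
            fh.write(f"{t.pool}\t{t.position}\t{t.kind}\t{t.s}\t{t.f0}\t"
                     f"{t.site_index}\t{freqs}\n")
    return vcf, popmap, truth
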