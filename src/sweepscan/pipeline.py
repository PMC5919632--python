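"""End-to-end orchestration of the two-step artificial-selection scan.

A run takes phased genotypes plus a population map (or simulates them),
applies QC and ancestral coding, then for every domestic pool:

1. positive-selection step - windowed |iHS| and CLR tracks with their
   permutation thresholds, outliers padded into 200 kb regions and merged
   into iHS-CLR regions;
2. differentiation step - window F_ST against the wild reference with its
   own permutation threshold and 200 kb regions; iHS-CLR regions
   overlapping an F_ST region become artificial-selection regions;
3. classification - solid-spine blocks and core haplotypes inside each
   artificial region, classed hard / soft / unclassified against the
   reference pool;

plus observed-heterozygosity tracks, optional gene annotation, and the
summary fractions.  Every random step is seeded, so re-running the same
configuration reproduces identical outputs.  The two-step design is
mandatory: a configuration without the F_ST step is refused.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import blocks as blocks_mod
from . import clr as clr_mod
from . import fst as fst_mod
from . import genotype_io
from . import ihs as ihs_mod
from . import regions as regions_mod
from . import report as report_mod
from . import simulate as sim_mod
from .types import QCConfig

log = logging.getLogger(__name__)

__all__ = ["default_config", "read_config", "run_pipeline", "scan_pool"]


def default_config() -> dict:
    return {
        "steps": "ihs,clr,fst",
        "seed": 1,
        "window": 10_000,
        "flank": 100_000,
        "region_pad": 100_000,
        "merge_gap": 200_000,
        "level": 0.05,
        "n_perm_fst": 1000,
        "n_perm_ihs": 1000,
        "n_perm_clr": 100,
        "maf_core": 0.05,
        "ehh_cutoff": 0.05,
        "dprime_min": 0.8,
        "core_freq_min": 0.8,
        "soft_floor": 0.125,
        "qc": True,
        "fill_missing": False,
    }


def read_config(path) -> dict:
    """Flat ``key=value`` configuration file; '#' starts a comment."""
    cfg = default_config()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line (expected key=value): {raw!r}")
            key, value = (x.strip() for x in line.split("=", 1))
            cfg[key] = _coerce(value)
    return cfg


def _coerce(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    if v.lower() in ("true", "false"):
        return v.lower() == "true"
    return v


def _validate(cfg: dict) -> None:
    steps = {s.strip() for s in str(cfg.get("steps", "")).split(",") if s.strip()}
    if "fst" not in steps:
        raise ValueError(
            "the two-step design is mandatory: config must keep the 'fst' step"
        )
    if not ({"ihs", "clr"} & steps):
        raise ValueError("at least one positive-selection step (ihs/clr) is required")
    cfg["_steps"] = steps
    has_input = "input_vcf" in cfg or "input_ped" in cfg
    if not has_input and not cfg.get("simulate", False):
        raise ValueError("config names neither input files nor simulate=true")


def _load_inputs(cfg: dict, out_dir: Path):
    if cfg.get("simulate", False):
        sweeps = []
        for item in str(cfg.get("sim_sweeps", "")).split(";"):
            item = item.strip()
            if not item:
                continue
            f = item.split(":")
            sweeps.append(sim_mod.SweepSpec(
                position=int(f[0]), kind=f[1], s=float(f[2]),
                f0=float(f[3]) if len(f) > 3 else 0.2,
            ))
        sim_cfg = sim_mod.SimConfig(
            n_ancestral=int(cfg.get("sim_n_ancestral", 100)),
            n_per_pool=int(cfg.get("sim_n_per_pool", 50)),
            n_pools=int(cfg.get("sim_n_pools", 2)),
            n_sites=int(cfg.get("sim_n_sites", 8000)),
            chrom_length=int(cfg.get("sim_chrom_length", 10_000_000)),
            t_burnin=int(cfg.get("sim_t_burnin", 300)),
            t_split=int(cfg.get("sim_t_split", 200)),
            sweeps=sweeps,
            seed=int(cfg["seed"]),
        )
        vt, hm, pm, ids, truths = sim_mod.simulate(sim_cfg)
        sim_mod.emit(vt, hm, pm, ids, truths, out_dir / "simulated")
        return vt, hm, pm, ids
    if "input_vcf" in cfg:
        vt, hm, ids = genotype_io.read_genotypes(cfg["input_vcf"], "vcf")
    else:
        vt, hm, ids = genotype_io.read_genotypes(cfg["input_ped"], "plink-text")
    pm = genotype_io.read_population_map(cfg["popmap"])
    missing_pm = [i for i in ids if i not in pm.pool_of]
    if missing_pm:
        raise ValueError(f"individuals absent from population map: {missing_pm[:5]}")
    return vt, hm, pm, ids


def scan_pool(vt, hm, pm, ids, pool: str, cfg: dict, seed: int):
    """One domestic pool's scans, thresholds, regions and classification."""
    width = int(cfg["window"])
    level = float(cfg["level"])
    chrom_lengths = {c: int(vt.pos[vt.chrom == c].max()) for c in vt.chromosomes()}
    hm_pool = genotype_io.pool_haplotypes(hm, pm, pool, ids)
    hm_ref = genotype_io.pool_haplotypes(hm, pm, pm.reference_pool, ids)
    hm_dom = genotype_io.pool_haplotypes(hm, pm, pm.domestic_pools(), ids)
    out: dict = {"pool": pool}
    steps = cfg["_steps"]

    psr = {}
    if "ihs" in steps:
        ihs_df = ihs_mod.ihs_scan(hm_pool, vt, cutoff=float(cfg["ehh_cutoff"]),
                                  maf_core=float(cfg["maf_core"]))
        track = ihs_mod.window_abs_ihs(ihs_df, width)
        spec = regions_mod.permute_ihs_null(ihs_df, n_perm=int(cfg["n_perm_ihs"]),
                                            seed=seed, level=level, width=width)
        outliers = regions_mod.call_outliers(track, spec)
        psr["PSR_iHS"] = regions_mod.build_psr(outliers, "PSR_iHS",
                                               pad=int(cfg["region_pad"]),
                                               chrom_lengths=chrom_lengths)
        out.update(ihs_sites=ihs_df, ihs_track=track, ihs_threshold=spec,
                   ihs_outliers=outliers)
    if "clr" in steps:
        table = clr_mod.SweepLikelihoodTable.build(clr_mod.background_sfs(hm_pool))
        track = clr_mod.clr_scan(hm_pool, vt, grid=width, flank=int(cfg["flank"]),
                                 table=table)
        spec = regions_mod.permute_clr_null(hm_pool, vt, n_perm=int(cfg["n_perm_clr"]),
                                            seed=seed + 1, level=level, grid=width,
                                            flank=int(cfg["flank"]), table=table)
        outliers = regions_mod.call_outliers(track, spec)
        psr["PSR_CLR"] = regions_mod.build_psr(outliers, "PSR_CLR",
                                               pad=int(cfg["region_pad"]),
                                               chrom_lengths=chrom_lengths)
        out.update(clr_track=track, clr_threshold=spec, clr_outliers=outliers)

    ihs_clr = regions_mod.merge_ihs_clr(
        psr.get("PSR_iHS", regions_mod._empty_regions("PSR_iHS")),
        psr.get("PSR_CLR", regions_mod._empty_regions("PSR_CLR")),
        gap=int(cfg["merge_gap"]),
    )

    fst_track = fst_mod.fst_track(hm, vt, pm, pool, ids, width)
    fst_spec = regions_mod.permute_fst_null(hm, vt, pm, pool, ids,
                                            n_perm=int(cfg["n_perm_fst"]),
                                            seed=seed + 2, level=level, width=width)
    fst_outliers = regions_mod.call_outliers(fst_track, fst_spec)
    fst_regions = regions_mod.build_psr(fst_outliers, "FST",
                                        pad=int(cfg["region_pad"]),
                                        chrom_lengths=chrom_lengths)
    artificial = regions_mod.intersect_artificial(ihs_clr, fst_regions)

    het_track = fst_mod.window_het_and_freq(hm, vt, pm, pool, ids, width)

    calls = []
    region_classes = []
    for rec in artificial.itertuples(index=False):
        region = (rec.chrom, int(rec.start), int(rec.end))
        region_calls, region_class = blocks_mod.classify_region(
            hm_pool, hm_ref, vt, region,
            dprime_min=float(cfg["dprime_min"]),
            core_freq_min=float(cfg["core_freq_min"]),
            soft_floor=float(cfg["soft_floor"]),
            hm_spine=hm_dom,
        )
        calls.extend(region_calls)
        region_classes.append(region_class)
    artificial = artificial.assign(classification=region_classes
                                   if region_classes else pd.Series(dtype=object))

    out.update(psr=psr, ihs_clr=ihs_clr, fst_track=fst_track,
               fst_threshold=fst_spec, fst_outliers=fst_outliers,
               fst_regions=fst_regions, artificial=artificial,
               het_track=het_track, sweep_calls=calls)
    return out


def run_pipeline(config, out_dir=None) -> dict:
    """Run the full scan; writes TSV/BED artifacts and returns all results.

    *config* is a dict or the path of a flat key=value file.  The result
    maps each domestic pool to its :func:`scan_pool` output, plus
    ``summary`` (selection fractions) and ``out_dir``.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    else:
        merged = default_config()
        merged.update(config)
        config = merged
    _validate(config)
    out_dir = Path(out_dir if out_dir is not None else config.get("out_dir", "scan_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])

    vt, hm, pm, ids = _load_inputs(config, out_dir)
    if config.get("qc", True):
        vt, hm, ids, qc_report = genotype_io.apply_qc(vt, hm, pm, ids, QCConfig())
        log.info("QC: removed %d individuals, %d SNPs",
                 qc_report.n_individuals_removed, qc_report.n_snps_removed)
    if config.get("fill_missing", False):
        hm = genotype_io.fill_missing(hm, pm, ids)
    if (hm < 0).any():
        raise ValueError("missing calls remain after QC; set fill_missing=true")
    vt, hm = genotype_io.derive_ancestral_coding(vt, hm, pm, ids)

    genes = None
    if "gff" in config:
        genes = annotate_mod.load_gene_models(config["gff"])
        annotate_mod.classify_snp_location(vt, genes).to_csv(
            out_dir / "snp_categories.tsv", sep="\t", index=False)

    results: dict = {"out_dir": out_dir, "pools": {}}
    positive, artificial = {}, {}
    for k, pool in enumerate(pm.domestic_pools()):
        res = scan_pool(vt, hm, pm, ids, pool, config, seed=seed + 100 * (k + 1))
        results["pools"][pool] = res
        positive[pool] = res["ihs_clr"]
        artificial[pool] = res["artificial"]
        pdir = out_dir / pool
        pdir.mkdir(exist_ok=True)
        for name in ("ihs_track", "clr_track", "fst_track", "het_track"):
            if name in res:
                res[name].to_csv(pdir / f"{name}.tsv", sep="\t", index=False)
        if "ihs_sites" in res:
            res["ihs_sites"].to_csv(pdir / "ihs_sites.tsv", sep="\t", index=False)
        regions_mod.write_bed(pdir / "ihs_clr_regions.bed", res["ihs_clr"])
        regions_mod.write_bed(pdir / "fst_regions.bed", res["fst_regions"])
        regions_mod.write_bed(pdir / "artificial_regions.bed", res["artificial"])
        pd.DataFrame([c.__dict__ for c in res["sweep_calls"]]).to_csv(
            pdir / "sweep_calls.tsv", sep="\t", index=False)
        if genes is not None:
            gmap = annotate_mod.genes_in_regions(res["artificial"], genes)
            with open(pdir / "region_genes.tsv", "w") as fh:
                fh.write("chrom\tstart\tend\tgenes\n")
                for (c, s, e), gl in gmap.items():
                    fh.write(f"{c}\t{s}\t{e}\t{','.join(gl)}\n")

    nonzero = [p for p in positive if len(positive[p]) > 0]
    if nonzero:
        summaries = report_mod.summarize_pools(
            {p: positive[p] for p in nonzero}, artificial)
        results["summary"] = report_mod.selection_fractions(summaries)
        results["summary"]["per_pool"].to_csv(out_dir / "summary.tsv",
                                              sep="\t", index=False)
    return results
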