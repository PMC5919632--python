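"""Shared fixtures: tiny hand-built datasets and one small simulated genome."""

import numpy as np
import pytest

from sweepscan.types import PopulationMap, VariantTable


def make_vt(pos, chrom="1", **kw):
    pos = list(pos)
    return VariantTable(
        chrom=[chrom] * len(pos),
        pos=pos,
        snp_id=[f"s{i}" for i in range(len(pos))],
        allele0=["A"] * len(pos),
        allele1=["G"] * len(pos),
        **kw,
    )


@pytest.fixture
def tiny_vt():
    return make_vt([100, 5000, 10_000, 12_500, 30_000])


@pytest.fixture
def two_pool_pm():
    return PopulationMap(
        pool_of={"w1": "WILD", "w2": "WILD", "d1": "DOM", "d2": "DOM"},
        reference_pool="WILD",
    )


@pytest.fixture(scope="session")
def small_sim():
    """One seeded neutral simulation shared by read-only tests."""
    from sweepscan.simulate import SimConfig, simulate

    cfg = SimConfig(seed=42, n_sites=1200, chrom_length=1_500_000,
                    t_burnin=150, t_split=20)
    vt, hm, pm, ids, truths = simulate(cfg)
    return vt, hm, pm, ids, truths


@pytest.fixture(scope="session")
def sweep_sim():
    """One seeded three-pool simulation with a hard and a soft sweep."""
    from sweepscan.simulate import SimConfig, SweepSpec, simulate

    cfg = SimConfig(seed=8, n_sites=1600, chrom_length=2_000_000, n_pools=3,
                    t_burnin=300, t_split=50,
                    sweeps=[SweepSpec(500_000, "hard", 0.3),
                            SweepSpec(1_500_000, "soft", 0.3, 0.25)])
    vt, hm, pm, ids, truths = simulate(cfg)
    return vt, hm, pm, ids, truths
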