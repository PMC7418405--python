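"""Shared synthetic worlds for the test suite.

Heavier fixtures are session-scoped so the cost of building panels is
paid once.  All worlds are fully deterministic.
"""

import numpy as np
import pytest

from ldcontam.panel import HaplotypePanel, build_panel
from ldcontam.simulator import (SimScenario, simulate_haplotype_pool,
                                simulate_individual, simulate_reads)

from oracle_utils import random_consistent_panel


@pytest.fixture(scope="session")
def small_pool():
    """100 diploids, 40 blocks x 5 SNPs = 200 SNPs (fast unit tests)."""
    scenario = SimScenario(n_blocks=40, snps_per_block=5, panel_size=100, seed=7)
    return simulate_haplotype_pool(scenario), scenario


@pytest.fixture(scope="session")
def small_panel(small_pool):
    pool, _ = small_pool
    return build_panel(pool.genotype_matrix(), pool.snps)


@pytest.fixture(scope="session")
def synthetic_panel():
    """Self-consistent artificial panel (50 pairs over 22 chromosomes)."""
    return HaplotypePanel(pairs=random_consistent_panel(50, seed=3))


@pytest.fixture(scope="session")
def recovery_world():
    """Moderate world for parameter-recovery and calibration runs.

    6600 blocks x 5 SNPs (33,000 SNPs), 2000-diploid reference cohort
    (so panel-frequency noise is a minor bias source), mean depth 2.5,
    damage rate 0.1 -- deep enough that the damage classes carry real
    information, sparse enough that per-pair likelihoods stay in the
    quasi-linear bias regime.
    """
    scenario = SimScenario(n_blocks=6600, snps_per_block=5, panel_size=2000,
                           mean_depth=2.5, alpha_true=0.05, damage_rate=0.1,
                           seed=42)
    pool = simulate_haplotype_pool(scenario)
    panel = build_panel(pool.genotype_matrix(), pool.snps)
    return pool, panel, scenario


def sample_from_world(world, alpha, rep, damage_rate=None, mean_depth=None,
                      inbreeding_f=0.0, contaminant_mode="modern"):
    """One replicate: fresh base + contaminant individuals, then reads."""
    pool, panel, scenario = world
    params = scenario.to_dict()
    params.update(alpha_true=alpha, inbreeding_f=inbreeding_f,
                  contaminant_mode=contaminant_mode)
    if damage_rate is not None:
        params["damage_rate"] = damage_rate
    if mean_depth is not None:
        params["mean_depth"] = mean_depth
    sc = SimScenario(**params)
    base = simulate_individual(pool, inbreeding_f, seed=10_000 + rep)
    cont = simulate_individual(pool, 0.0, seed=20_000 + rep)
    if contaminant_mode == "ancient_damaged":
        from ldcontam.simulator import simulate_ancient_contaminant
        counts = simulate_ancient_contaminant(base, cont, sc, pool.snps,
                                              seed=30_000 + rep)
    else:
        counts = simulate_reads(base, cont, sc, pool.snps, seed=30_000 + rep)
    return counts
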