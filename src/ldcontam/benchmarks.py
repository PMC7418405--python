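"""Standard desk-scale synthetic benchmark scenarios.

These functions define the package's reference evaluation world: a
founder-copying cohort yielding roughly 200,000 LD pairs (88,000 blocks
of 5 SNPs = 440,000 SNPs over 22 pseudo-chromosomes, 4 founders per
block, 150 panel diploids), with samples sequenced to about 500,000
sequences over panel SNPs -- the sequence count at which the estimator
is expected to resolve contamination to about a percentage point.  The
implied per-SNP depth (500000 / n_snps, about 1.1x) keeps the sample in
the sparse-coverage regime where the panel-mismatch bias acts as the
linear shift the damage correction assumes; concentrating the same
sequence total on far fewer SNPs would not.

All randomness derives from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import SiteCounts, damage_summary
from .estimator import ContamEstimate, estimate
from .panel import HaplotypePanel, build_panel
from .simulator import (HaplotypePool, SimScenario, simulate_haplotype_pool,
                        simulate_individual, simulate_reads)

#: stated benchmark world
N_BLOCKS = 88_000
SNPS_PER_BLOCK = 5
PANEL_SIZE = 150
N_SEQUENCES = 500_000
ALPHA_TRUE = 0.05
DAMAGE_RATE = 0.10
SWEEP_ALPHA = 0.03
SWEEP_DAMAGE_RATES = (0.02, 0.05, 0.075)


def _spawn_ints(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


@dataclass
class BenchmarkWorld:
    """Pool, panel and held-out individuals of the benchmark scenario."""

    scenario: SimScenario
    pool: HaplotypePool
    panel: HaplotypePanel
    base_genotype: np.ndarray
    contaminant_genotype: np.ndarray
    benchmark_genotype: np.ndarray
    read_seed: int
    bench_seed: int

    @property
    def mean_depth(self) -> float:
        return self.scenario.mean_depth


def build_benchmark_world(seed: int, n_blocks: int = N_BLOCKS,
                          snps_per_block: int = SNPS_PER_BLOCK,
                          panel_size: int = PANEL_SIZE,
                          n_sequences: int = N_SEQUENCES,
                          alpha_true: float = ALPHA_TRUE,
                          damage_rate: float = DAMAGE_RATE) -> BenchmarkWorld:
    """Build the shared pool, panel and held-out individuals.

    The base, contaminant and benchmark individuals are fresh draws from
    the pool's haplotype distribution and are therefore not part of the
    reference cohort the panel is estimated from.
    """
    s_pool, s_base, s_cont, s_bench, s_reads, s_breads = _spawn_ints(seed, 6)
    n_snps = n_blocks * snps_per_block
    scenario = SimScenario(
        n_founder_haplotypes=4, n_blocks=n_blocks, snps_per_block=snps_per_block,
        panel_size=panel_size, alpha_true=alpha_true, damage_rate=damage_rate,
        mean_depth=n_sequences / n_snps, seed=s_pool)
    pool = simulate_haplotype_pool(scenario)
    panel = build_panel(pool.genotype_matrix(), pool.snps,
                        population_label="benchmark-pool")
    base = simulate_individual(pool, 0.0, seed=s_base)
    cont = simulate_individual(pool, 0.0, seed=s_cont)
    bench = simulate_individual(pool, 0.0, seed=s_bench)
    return BenchmarkWorld(scenario=scenario, pool=pool, panel=panel,
                          base_genotype=base, contaminant_genotype=cont,
                          benchmark_genotype=bench, read_seed=s_reads,
                          bench_seed=s_breads)


def sample_counts(world: BenchmarkWorld, alpha_true: float = None,
                  damage_rate: float = None, seed: int = None) -> SiteCounts:
    """Contaminated sequence counts for the benchmark base individual."""
    sc = world.scenario
    scenario = SimScenario(**{**sc.to_dict(),
                              "alpha_true": sc.alpha_true if alpha_true is None else alpha_true,
                              "damage_rate": sc.damage_rate if damage_rate is None else damage_rate})
    return simulate_reads(world.base_genotype, world.contaminant_genotype,
                          scenario, world.pool.snps,
                          seed=world.read_seed if seed is None else seed)


def benchmark_alpha(world: BenchmarkWorld) -> float:
    """Raw estimate of the uncontaminated held-out benchmark individual."""
    sc = world.scenario
    scenario = SimScenario(**{**sc.to_dict(), "alpha_true": 0.0})
    counts = simulate_reads(world.benchmark_genotype, world.contaminant_genotype,
                            scenario, world.pool.snps, seed=world.bench_seed)
    est = estimate(counts, world.panel, mode="none")
    return est.alpha_raw


def damage_corrected_run(world: BenchmarkWorld, counts: SiteCounts = None) -> ContamEstimate:
    """Damage-corrected estimate (with jackknife SE) on the benchmark sample."""
    if counts is None:
        counts = sample_counts(world)
    return estimate(counts, world.panel, mode="damage")


def external_corrected_run(world: BenchmarkWorld,
                           counts: SiteCounts = None) -> ContamEstimate:
    """Externally corrected estimate on the same benchmark sample."""
    if counts is None:
        counts = sample_counts(world)
    bench = benchmark_alpha(world)
    return estimate(counts, world.panel, mode="external", benchmark=bench)


def damage_rate_sweep(world: BenchmarkWorld, alpha_true: float = SWEEP_ALPHA,
                      damage_rates=SWEEP_DAMAGE_RATES, seed: int = None):
    """Damage-corrected SEs across damage rates at 0.5x-equivalent depth.

    "0.5x-equivalent" is a sequence count of ~500,000 over panel SNPs
    (what 0.5x coverage yields on a ~1.2M-SNP genome-wide panel), i.e.
    the world's standard depth.  Returns ``{rate: ContamEstimate}``.
    """
    seeds = _spawn_ints(world.read_seed if seed is None else seed,
                        len(tuple(damage_rates)))
    out = {}
    for rate, s in zip(damage_rates, seeds):
        counts = sample_counts(world, alpha_true=alpha_true, damage_rate=rate,
                               seed=s)
        out[rate] = estimate(counts, world.panel, mode="damage")
    return out
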