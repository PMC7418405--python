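"""Synthetic haplotype pools, individuals and contaminated sequence counts.

The generator stands in for a real reference cohort: instead of
downloading phased genotypes, it builds a founder-copying block model
that produces genuine linkage disequilibrium.  Each block carries a small
number of founder haplotypes (alleles drawn per SNP from a founder
frequency sampler); cohort haplotypes copy one founder per block, chosen
with block-specific Dirichlet weights.  Blocks are independent (no
cross-block LD) and are assigned round-robin to 22 pseudo-chromosomes.

Sequence data mimic the spike-in experiments used to validate
contamination estimators: per SNP, endogenous depth is Poisson; each
endogenous sequence draws its allele from the base genotype (heterozygous
sites 50/50), is flagged damaged with probability ``damage_rate``; and for
each endogenous *undamaged* sequence a contaminant sequence is added with
probability ``alpha / (1 - alpha)`` (so contaminants make up a fraction
``alpha`` of undamaged sequences), its allele drawn from the contaminant
genotype.  Contaminant sequences are undamaged in the modern-contaminant
mode.  The ancient-contaminant variant instead marks a uniform 5%
downsample of *all* sequences as damaged after spiking, so the damaged
fraction carries contaminants at the same rate as the whole -- the
scenario in which a damage-restricted correction is blind.

Damage is a per-sequence Bernoulli flag, not a per-base C-to-T process;
the estimator consumes only the flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .counts import COUNT_COLUMNS, SiteCounts

N_CHROM = 22
_BLOCK_SPACING = 2_000_000   # bp between block starts: beyond the default
_SNP_SPACING = 1_000         # 1 Mb pairing window, so blocks never pair


@dataclass
class SimScenario:
    """Parameterisation of one synthetic contamination experiment.

    Defaults describe a small but realistic desk-scale world: 4 founder
    haplotypes per block (strong block LD, as after a bottleneck), 50
    blocks of 10 common SNPs spread over 22 pseudo-chromosomes, a cohort
    of 100 diploids, 5% contamination, 5% per-sequence damage and 2x mean
    depth.  Founder allele frequencies are Uniform(0.1, 0.9), matching
    the common-SNP ascertainment of reference panels.
    """

    n_founder_haplotypes: int = 4
    n_blocks: int = 50
    snps_per_block: int = 10
    panel_size: int = 100
    alpha_true: float = 0.05
    damage_rate: float = 0.05
    mean_depth: float = 2.0
    contaminant_mode: str = "modern"      # modern | ancient_damaged | multiple
    n_contaminants: int = 1               # m, for contaminant_mode="multiple"
    inbreeding_f: float = 0.0
    founder_freq_lo: float = 0.1
    founder_freq_hi: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.alpha_true < 0.5):
            raise ValueError("alpha_true must lie in [0, 0.5)")
        if not (0.0 <= self.damage_rate <= 1.0):
            raise ValueError("damage_rate must lie in [0, 1]")
        for name in ("n_founder_haplotypes", "n_blocks", "snps_per_block",
                     "panel_size", "n_contaminants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HaplotypePool:
    """Cohort haplotypes with block structure.

    ``haplotypes`` is (2 * panel_size, n_snps) of 0/1 alleles;
    ``founders`` (n_blocks, n_founder, snps_per_block) holds the founder
    alleles; ``lineage`` (2 * panel_size, n_blocks) records which founder
    each haplotype copies in each block.
    """

    haplotypes: np.ndarray
    snps: pd.DataFrame
    block_id: np.ndarray
    founders: np.ndarray
    lineage: np.ndarray
    block_weights: np.ndarray

    @property
    def n_blocks(self) -> int:
        return self.founders.shape[0]

    def genotype_matrix(self) -> np.ndarray:
        """Diploid dosages of the cohort, (panel_size, n_snps)."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(float)

    def sample_ids(self):
        return np.array([f"panel{i}" for i in range(self.haplotypes.shape[0] // 2)])


def _snp_metadata(scenario: SimScenario, rng: np.random.Generator) -> pd.DataFrame:
    n_snps = scenario.n_blocks * scenario.snps_per_block
    block = np.repeat(np.arange(scenario.n_blocks), scenario.snps_per_block)
    chrom = block % N_CHROM + 1
    block_rank = block // N_CHROM
    within = np.tile(np.arange(scenario.snps_per_block), scenario.n_blocks)
    pos = 1 + block_rank * _BLOCK_SPACING + within * _SNP_SPACING
    bases = np.array(list("ACGT"))
    ref_ix = rng.integers(0, 4, n_snps)
    alt_ix = (ref_ix + rng.integers(1, 4, n_snps)) % 4
    return pd.DataFrame({"chrom": chrom.astype(int), "pos": pos.astype(int),
                         "ref": bases[ref_ix], "alt": bases[alt_ix]})


def perturb_freqs(freqs, scale: float, seed: int = 0) -> np.ndarray:
    """Logit-normal perturbation of allele frequencies.

    Used to manufacture ancestry-mismatched reference pools: a second
    population whose founder frequencies drift from the first by
    ``scale`` standard deviations on the logit scale.
    """
    rng = np.random.default_rng(seed)
    f = np.clip(np.asarray(freqs, dtype=float), 1e-6, 1 - 1e-6)
    logit = np.log(f / (1 - f)) + rng.normal(0.0, scale, f.shape)
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_haplotype_pool(scenario: SimScenario, founder_freqs=None):
    """Draw founders and a cohort of copying haplotypes.

    Returns ``HaplotypePool``; identical scenarios (same seed) are
    bit-reproducible.  ``founder_freqs`` (n_blocks, snps_per_block)
    overrides the scenario's frequency sampler, e.g. with perturbed
    frequencies from :func:`perturb_freqs` to build a mismatched pool.
    """
    rng = np.random.default_rng(scenario.seed)
    snps = _snp_metadata(scenario, rng)
    nb, spb, nf = scenario.n_blocks, scenario.snps_per_block, scenario.n_founder_haplotypes
    freqs = rng.uniform(scenario.founder_freq_lo, scenario.founder_freq_hi, (nb, spb))
    if founder_freqs is not None:
        freqs = np.asarray(founder_freqs, dtype=float)
        if freqs.shape != (nb, spb):
            raise ValueError("founder_freqs must have shape (n_blocks, snps_per_block)")
    founders = (rng.random((nb, nf, spb)) < freqs[:, None, :]).astype(np.int8)
    weights = rng.dirichlet(np.ones(nf), size=nb)
    n_hap = 2 * scenario.panel_size
    lineage = _sample_lineages(rng, weights, n_hap)
    haplotypes = _copy_founders(founders, lineage)
    return HaplotypePool(haplotypes=haplotypes, snps=snps,
                         block_id=np.repeat(np.arange(nb), spb),
                         founders=founders, lineage=lineage, block_weights=weights)


def _sample_lineages(rng, weights: np.ndarray, n_hap: int) -> np.ndarray:
    """Founder lineage per (haplotype, block) from per-block weights."""
    nb, nf = weights.shape
    cum = np.cumsum(weights, axis=1)
    u = rng.random((n_hap, nb))
    lineage = np.empty((n_hap, nb), dtype=np.int32)
    chunk = max(1, 50_000_000 // max(nb * nf, 1))
    for lo in range(0, n_hap, chunk):
        hi = min(lo + chunk, n_hap)
        lineage[lo:hi] = (u[lo:hi, :, None] > cum[None, :, :]).sum(axis=2)
    return lineage


def _copy_founders(founders: np.ndarray, lineage: np.ndarray) -> np.ndarray:
    """Haplotypes (n_hap, nb * spb) copying founder alleles blockwise."""
    nb, nf, spb = founders.shape
    n_hap = lineage.shape[0]
    out = np.empty((n_hap, nb * spb), dtype=np.int8)
    block_ix = np.arange(nb)
    chunk = max(1, 100_000_000 // max(nb * spb, 1))
    for lo in range(0, n_hap, chunk):
        hi = min(lo + chunk, n_hap)
        out[lo:hi] = founders[block_ix[None, :], lineage[lo:hi], :].reshape(
            hi - lo, nb * spb)
    return out


def simulate_individual(pool: HaplotypePool, inbreeding_f: float = 0.0,
                        seed: int = 0) -> np.ndarray:
    """Diploid genotype vector of a fresh individual drawn from the pool.

    Two haplotypes are sampled per block (blocks are unlinked, mimicking
    distant chromosome segments).  With probability ``inbreeding_f`` per
    block the second haplotype is drawn from the same founder lineage as
    the first, making the block homozygous by descent.
    """
    if pool.haplotypes.shape[0] == 0:
        raise ValueError("empty haplotype pool")
    rng = np.random.default_rng(seed)
    nb = pool.n_blocks
    spb = pool.founders.shape[2]
    n_hap = pool.haplotypes.shape[0]
    i = rng.integers(n_hap, size=nb)
    j = rng.integers(n_hap, size=nb)
    if inbreeding_f > 0:
        ibd = rng.random(nb) < inbreeding_f
        # draw the second haplotype from the same founder lineage as the first
        lin_i = pool.lineage[i, np.arange(nb)]
        for b in np.flatnonzero(ibd):
            same = np.flatnonzero(pool.lineage[:, b] == lin_i[b])
            j[b] = same[rng.integers(len(same))]
    cols = np.arange(nb * spb)
    blk = cols // spb
    hap1 = pool.haplotypes[i[blk], cols]
    hap2 = pool.haplotypes[j[blk], cols]
    return (hap1 + hap2).astype(np.int8)


def _allele_split(n: np.ndarray, genotype: np.ndarray, rng) -> np.ndarray:
    """Number of alt-allele sequences among n draws from a diploid genotype."""
    p = np.asarray(genotype, dtype=float) / 2.0
    return rng.binomial(n, p)


def _to_sitecounts(snps: pd.DataFrame, nru, nau, nrd, nad) -> SiteCounts:
    df = snps[["chrom", "pos", "ref", "alt"]].copy()
    df["nref_und"] = np.asarray(nru, dtype=int)
    df["nalt_und"] = np.asarray(nau, dtype=int)
    df["nref_dam"] = np.asarray(nrd, dtype=int)
    df["nalt_dam"] = np.asarray(nad, dtype=int)
    return SiteCounts(df[COUNT_COLUMNS])


def simulate_reads(base_genotype, contaminant_genotypes, scenario: SimScenario,
                   snps: pd.DataFrame, seed: int = None,
                   depth_profile=None) -> SiteCounts:
    """Spike contaminant sequences into simulated endogenous sequences.

    Per SNP: endogenous depth ~ Poisson(``mean_depth``); each endogenous
    sequence draws its allele from the base genotype and a damage flag
    ~ Bernoulli(``damage_rate``); for every endogenous undamaged sequence
    a contaminant sequence (undamaged, allele from the contaminant
    genotype) is added with probability ``alpha / (1 - alpha)``, giving
    contaminants an expected share ``alpha`` of undamaged sequences.  In
    ``multiple`` mode each added sequence picks one of the contaminant
    genotypes uniformly.

    Parameters
    ----------
    contaminant_genotypes : array (n_snps,) or (m, n_snps)
    depth_profile : array (n_snps,), optional
        Per-SNP expected depth overriding the scalar ``mean_depth``.
    """
    if scenario.alpha_true >= 0.5:
        raise ValueError("alpha_true must be < 0.5")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    base = np.asarray(base_genotype)
    n_snps = base.shape[0]
    cont = np.atleast_2d(np.asarray(contaminant_genotypes))
    mean = np.full(n_snps, scenario.mean_depth) if depth_profile is None \
        else np.asarray(depth_profile, dtype=float)

    n_endo = rng.poisson(mean)
    n_alt = _allele_split(n_endo, base, rng)
    n_ref = n_endo - n_alt
    alt_dam = rng.binomial(n_alt, scenario.damage_rate)
    ref_dam = rng.binomial(n_ref, scenario.damage_rate)
    n_und = n_endo - alt_dam - ref_dam

    rate = scenario.alpha_true / (1.0 - scenario.alpha_true)
    n_cont = rng.binomial(n_und, rate)
    if cont.shape[0] == 1:
        cont_alt = _allele_split(n_cont, cont[0], rng)
    else:
        m = cont.shape[0]
        split = rng.multinomial(n_cont, np.full(m, 1.0 / m))  # (n_snps, m)
        cont_alt = np.zeros(n_snps, dtype=np.int64)
        for j in range(m):
            cont_alt += rng.binomial(split[:, j], cont[j] / 2.0)
    nru = (n_ref - ref_dam) + (n_cont - cont_alt)
    nau = (n_alt - alt_dam) + cont_alt
    return _to_sitecounts(snps, nru, nau, ref_dam, alt_dam)


def simulate_ancient_contaminant(base_genotype, contaminant_genotype,
                                 scenario: SimScenario, snps: pd.DataFrame,
                                 downsample_frac: float = 0.05,
                                 seed: int = None) -> SiteCounts:
    """Ancient-contaminant scenario: damage by uniform downsampling.

    All sequences (endogenous plus contaminant, spiked at
    ``alpha / (1 - alpha)`` per endogenous sequence) are generated without
    damage flags; then a uniform random fraction ``downsample_frac`` of
    *all* sequences is marked damaged, so the damaged subset carries
    contaminant sequences at the same rate as the whole dataset.  This is
    the regime where a damage-restricted correction absorbs the
    contamination signal entirely.
    """
    if scenario.alpha_true >= 0.5:
        raise ValueError("alpha_true must be < 0.5")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    base = np.asarray(base_genotype)
    cont = np.asarray(contaminant_genotype)
    n_snps = base.shape[0]
    mean = np.full(n_snps, scenario.mean_depth)

    n_endo = rng.poisson(mean)
    endo_alt = _allele_split(n_endo, base, rng)
    rate = scenario.alpha_true / (1.0 - scenario.alpha_true)
    n_cont = rng.binomial(n_endo, rate)
    cont_alt = _allele_split(n_cont, cont, rng)

    ref_tot = (n_endo - endo_alt) + (n_cont - cont_alt)
    alt_tot = endo_alt + cont_alt
    ref_dam = rng.binomial(ref_tot, downsample_frac)
    alt_dam = rng.binomial(alt_tot, downsample_frac)
    return _to_sitecounts(snps, ref_tot - ref_dam, alt_tot - alt_dam,
                          ref_dam, alt_dam)


def simulate_counts(scenario: SimScenario):
    """End-to-end convenience: pool, base/contaminant individuals, counts.

    Seeds for the individuals and reads are spawned deterministically
    from ``scenario.seed``.  Returns ``(pool, base, contaminants, counts)``
    where ``contaminants`` is an (m, n_snps) genotype array.
    """
    ss = np.random.SeedSequence(scenario.seed)
    s_base, s_cont, s_reads = [int(s.generate_state(1)[0] % (2 ** 31))
                               for s in ss.spawn(3)]
    pool = simulate_haplotype_pool(scenario)
    base = simulate_individual(pool, scenario.inbreeding_f, seed=s_base)
    m = scenario.n_contaminants if scenario.contaminant_mode == "multiple" else 1
    contaminants = np.stack([
        simulate_individual(pool, 0.0, seed=s_cont + j) for j in range(m)])
    if scenario.contaminant_mode == "ancient_damaged":
        counts = simulate_ancient_contaminant(base, contaminants[0], scenario,
                                              pool.snps, seed=s_reads)
    else:
        counts = simulate_reads(base, contaminants, scenario, pool.snps,
                                seed=s_reads)
    return pool, base, contaminants, counts
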