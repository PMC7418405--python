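# ldcontam

Estimation of autosomal contamination in ancient-DNA samples from the
breakdown of linkage disequilibrium (LD).

Contaminating DNA — from excavators, laboratory staff, reagents, or other
samples — carries haplotypes that are uncorrelated with those of the
individual being sequenced. Mixing such sequences into a library therefore
dilutes the LD expected between nearby SNPs. `ldcontam` measures that
dilution: it compares the two-SNP haplotype frequencies observed in a
sample's sequences against a reference panel's expectation and fits the
contamination fraction by maximum likelihood. Unlike X-chromosome
polymorphism methods, this works for female samples, and unlike
mitochondrial heterogeneity methods it measures the nuclear genome
directly. The intended users are ancient-DNA groups screening samples
(typically 0.1–1× coverage, capture or shotgun) before population-genetic
analysis.

## Model

For a pair of SNPs in high LD (genotype `r² ≥ 0.2` in the reference
cohort), let `h` be the population haplotype distribution over the four
allele configurations, estimated from unphased diploid genotype counts by
EM, and `h̃` the background distribution formed by multiplying the two
allele frequencies. Because low-coverage calls are pseudo-haploid, an
uncontaminated diploid yields sequence pairs from

```
q = h/2 + h̃/2
```

(the two sequences sample the same parental chromosome half the time).
With a contamination fraction α, a sequence pair is formed by two
same-source sequences (probability `(1−α)² + α²`, preserving LD) or one
of each (probability `2α(1−α)`, breaking LD):

```
T(α) = (1 − 2α + 2α²) · q  +  2α(1−α) · h̃
```

α is estimated by scanning a grid from −0.1 to 0.5 in steps of 1e-4 and
maximizing the summed per-pair multinomial LOD score relative to α = 0
(negative values absorb the extra LD created by inbreeding). Every
combination of one sequence at each SNP of a pair is one observation;
observations are treated as independent, and the induced correlation is
absorbed by a weighted delete-one-chromosome jackknife that provides the
standard error.

Reference-panel mismatch shifts the raw estimate by an amount `k`. Two
corrections are provided:

* **damage mode** — sequence pairs are stratified by the C-to-T damage
  status of their sequences into UU / DU / DD classes with effective
  parameters `α + k`, `α/2 + k`, `k` (damaged sequences are assumed
  authentically ancient, hence uncontaminated); the summed likelihood is
  maximized jointly over (α, k) and the result rescaled by
  `(1 − damage rate)` to refer to all sequences;
* **external mode** — the raw estimate of an assumed-uncontaminated,
  ancestry-matched benchmark individual is subtracted.

A raw estimate above 15% raises the `Very_High_Contamination` flag even
when the corrected estimate is low — the signature of heavy contamination
or of cross-contamination by another *ancient* (damaged) sample, which
the damage correction silently absorbs.

## Worked example

The package ships a founder-copying block simulator, so the full pipeline
runs without any external data:

```python
from ldcontam import (SimScenario, simulate_haplotype_pool, simulate_individual,
                      simulate_reads, build_panel, estimate)

scenario = SimScenario(n_blocks=6600, snps_per_block=5, panel_size=500,
                       mean_depth=2.5, alpha_true=0.05, damage_rate=0.1, seed=7)
pool = simulate_haplotype_pool(scenario)
panel = build_panel(pool.genotype_matrix(), pool.snps)

base = simulate_individual(pool, seed=1)          # held-out test individual
contaminant = simulate_individual(pool, seed=2)
counts = simulate_reads(base, contaminant, scenario, pool.snps, seed=3)

result = estimate(counts, panel, mode="damage")
```

which prints, via the fields of `result`:

```
panel pairs:      14918
sequences:        86046
damage rate:      0.0972
alpha_raw:        0.0606
k_hat:            -0.0050
alpha_corrected:  0.0661 +/- 0.0287
95% CI:           (0.0098, 0.1224)
warning:          (none)
```

The truth (5% contamination spiked into undamaged sequences) lies inside
the 95% interval; at this modest sequence count (~86k) the jackknife SE
is ~2.9 percentage points and shrinks roughly with the square root of
the number of sequences. The same steps are available from the shell
(`ldcontam simulate | build-panel | pulldown | match-panel | estimate`),
with sklearn-style estimator classes (`PanelBuilder`,
`ContaminationEstimator`) underneath for pipeline composition.

Typical real-data inputs are a reference panel in VCF or dosage-matrix
form (e.g. a 1000 Genomes population matched by the `match-panel`
shared-drift ranking) and a per-SNP count table pulled from a BAM with
`pulldown`, with damage status assigned upstream (PMD scores) or by the
terminal C-to-T heuristic.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
rebuilds the standard synthetic benchmark from scratch — a reference
cohort yielding ~200,000 LD pairs and held-out individuals sequenced to
~500,000 sequences over panel SNPs — and reports the jackknife standard
errors (percentage points) of the damage-corrected estimator at
α = 0.05, d = 0.1 (`t1`), the externally corrected estimator on the same
sample (`t2`), and the worst damage-corrected SE across damage rates
0.02–0.075 at α = 0.03 (`t3`). All quantities are computed at run time;
the run takes a few minutes on one CPU.
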