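# Methods

This note documents the statistical model, the numerical choices, and
what the synthetic data generator does and does not emulate. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Haplotype panels

A panel stores, per autosomal SNP pair in LD, the haplotype distribution
`h` over the four joint allele configurations, the allele frequencies
`p1, p2` (from which the background distribution `h̃ = p1 ⊗ p2` and the
pseudo-haploid distribution `q = h/2 + h̃/2` are always *recomputed*, so
the defining identity cannot drift through file round trips).

**Pair selection.** Pairs are same-chromosome, within a window
(default 1 Mb, flag-overridable), with squared Pearson correlation of
dosage vectors ≥ 0.2, computed over individuals non-missing at both
SNPs. SNPs are pre-filtered to autosomes with minor-allele frequency
strictly above 0.10. Overlapping pairs are all retained; the chromosome
jackknife absorbs the resulting dependence. Monomorphic or
under-observed (< 2 joint individuals) pairs are skipped and counted.

**EM.** `h` is estimated from unphased 3×3 dosage-count tables. The
latent variable is the parental-gamete decomposition; only the double
heterozygote is ambiguous. The E step distributes each cell's count over
ordered gamete pairs in proportion to `h(a₁,b₁)·h(a₂,b₂)`; the M step
renormalizes the expected gamete counts. Start is uniform (0.25); the
observed-data log-likelihood is non-decreasing (asserted per iteration
in tests); cells with zero model probability but positive counts are
floored at 1e-300 with a warning. When *only* double-heterozygote counts
exist the uniform start is a fixed point; the converged (uniform) result
is returned deterministically with a "degenerate EM" warning rather than
perturbed. Convergence uses the summed squared change between
iterations: default 1e-3 for a single table (the conventional per-call
threshold), but 1e-8 per pair inside `build_panel` — a panel-global
budget of 1e-3 spread over 10⁵–10⁶ pairs implies far tighter per-pair
convergence, and a loose per-pair stop leaves `h` biased toward the
uniform start, i.e. systematically weaker panel LD.

**Panel matching.** Candidate panels are ranked by the mean over shared
SNPs of `(x − o)(p − o)` (sample pseudo-haploid dosage, panel frequency,
outgroup frequency) — an outgroup-f3-style shared-drift statistic. The
pseudo-haploid draw is made once per sample and reused across panels.
No small-sample bias correction is applied (none is defined for this
use), and at least 1,000 shared SNPs are required.

**Harmonization.** Sample counts are matched to panel SNPs by exact
chrom+pos+REF/ALT; mismatches are dropped and reported in diagnostics.
No strand flipping is attempted, so A/T and C/G SNPs on opposite strands
are silently lost — a documented limitation; panels and pulldowns built
by this package are internally consistent.

## Pair observations

For each panel pair, every combination of one sequence at SNP1 and one
at SNP2 is an observation, assigned to damage class UU, DU (either
order), or DD. This full cross product is maximal use of the data and
reduces, per class, to bilinear products of the per-SNP count vectors,
so memory and scan cost are O(pairs × 4) regardless of depth. A seeded
hypergeometric subsampling cap per pair is available but off by default.
Sites covered in the sample but absent from the panel are ignored; the
panel defines the analysis universe.

## Estimation

The mixture `T(α) = (1 − 2α + 2α²) q + 2α(1−α) h̃` is scanned over
α ∈ [−0.1, 0.5] in steps of 1e-4; the LOD score is the summed per-pair
multinomial log-likelihood ratio against α = 0, reported in log10 units
(the conventional LOD base; the argmax is base-invariant). LOD(0) = 0
identically; argmax ties break toward the smaller α. `T` is evaluated on
the (h, h̃) basis, `T = ((1−2α+2α²)/2)·h + ((1+2α−2α²)/2)·h̃`, which is
algebraically identical when `q = h/2 + h̃/2` and keeps both weights
non-negative over the scan range.

**Damage correction.** The class likelihoods `L_UU(α+k)`, `L_DU(α/2+k)`,
`L_DD(k)` are summed and maximized over a deterministic coarse-to-fine
grid: coarse step 0.002 on each axis (α as above, k ∈ [−0.1, 0.3]), then
step 1e-4 within ±0.004 of the coarse optimum. Internally all grid
values live on an exact integer lattice (unit 5e-5 — the set closed
under α + k, α/2 + k, and k), and each class likelihood is a 1-D profile
curve cached per chromosome, so the 2-D passes are exact lookups and the
delete-one jackknife re-optimizations are nearly free. The fitted α is
the contamination rate among undamaged sequences and is multiplied by
`(1 − d)` (d = damaged fraction over panel SNPs) to refer to all
sequences. Fewer than 1,000 DD observations triggers an "insufficient
damaged data" warning; an optimum on the grid boundary warns rather than
errors (gross over-estimates above the warning threshold lead to sample
removal anyway).

**External correction.** `α_corrected = α_raw − α_benchmark`. The
`(1 − d)` rescale is *not* applied in external mode: the benchmark's raw
estimate is measured on the same all-sequences scale as the sample's, so
the subtraction is already consistent on that scale. Negative corrected
values are reported signed, with a floored-at-zero convenience column.

**Standard errors.** Weighted delete-one-chromosome jackknife (weights =
pooled pair-observation counts per chromosome; standard unequal-block
pseudovalue formula). It reduces to the textbook unweighted formula at
equal weights and to `|θ₁ − θ₂|/2` at two equal blocks. In damage mode
each deletion refits (α, k) and recomputes the deleted damage rate. At
least two chromosomes with observations are required.

**Warning.** `Very_High_Contamination` iff the *uncorrected* pooled-scan
estimate exceeds 0.15.

**Numerics.** Probabilities inside logs are floored at 1e-300 (a
module-level counter tracks floor events); accumulation is double
precision throughout. The scan is O(grid × pairs × 4) and handles
200,000 pairs in well under a minute per full scan on one CPU.

## Synthetic data

`SimScenario` describes a founder-copying block world: each block draws
`n_founder_haplotypes` founders (allele per SNP ~ Bernoulli with
frequency ~ Uniform(0.1, 0.9), matching common-SNP ascertainment), then
cohort haplotypes copy one founder per block with block-specific
Dirichlet(1) weights. Blocks are independent, assigned round-robin to 22
pseudo-chromosomes, spaced 2 Mb apart (outside the default pairing
window); SNPs sit 1 kb apart. Defaults (4 founders, 50 blocks × 5 SNPs,
100 diploids, α = 0.05, d = 0.05, depth 2×) are a small but realistic
screening scenario; benchmark functions scale the same world up.

Individuals are fresh draws of two haplotypes per block; with
probability `inbreeding_f` per block both come from the same founder
lineage (homozygosity by descent — copies carry no private mutations, so
such blocks are fully homozygous). Reads: endogenous depth ~
Poisson(mean depth) per SNP (a per-SNP depth profile can be supplied),
allele drawn from the genotype (heterozygous → 50/50), damage a
per-sequence Bernoulli(d) flag. Contaminants are spiked per endogenous
*undamaged* sequence with probability `α/(1−α)` — giving contaminants an
expected share α of undamaged sequences — drawn from the contaminant
genotype(s), always undamaged in modern mode. The ancient-contaminant
variant instead generates all sequences un-flagged and then marks a
uniform 5% downsample of *all* sequences damaged, so the damaged subset
carries contaminants at the full-data rate: the regime in which the
damage correction is structurally blind and only the raw score (and its
15% warning) can flag the sample.

**What the generator does not emulate.** Damage is a flag, not a
per-base C-to-T process (the estimator consumes only the flag);
sequencing error and reference bias are absent; depth is Poisson rather
than empirically overdispersed; LD has a hard block structure with no
decay, no cross-block correlation and unrealistically many near-perfect
pairs; and all cohort members share four founder lineages per block, so
everyone is distantly related. A green recovery test therefore
establishes correctness of the estimator's own model and machinery under
a faithful generative process — not robustness to base-calling error,
reference bias, or fine-scale recombination structure.

**Estimand scale.** The spike rate α refers to undamaged sequences; the
damage-corrected output refers to all sequences and equals
`α·(1−d)` in truth. Recovery and calibration tests compare on the
undamaged-sequence scale (`alpha_corrected/(1−d)` vs α) to avoid mixing
conventions; at d = 0.1 the scales differ by exactly 10% of α.

## Benchmark world and known limitations

The acceptance benchmark (ldcontam.benchmarks) uses 88,000 blocks × 5
SNPs = 440,000 SNPs, 150 panel diploids, ~198,000 pairs at r² ≥ 0.2, and
samples of ~525,000 sequences (mean depth ≈ 1.14). Depth near 1× is
deliberate: concentrating the same sequence budget on far fewer SNPs
makes each pair's likelihood concentrate on the test individual's own
haplotype instantiation, inflating the panel-mismatch shift k beyond the
linear, class-additive regime that the damage correction assumes. The
same mechanism mildly attenuates estimates above ~2× depth; real ancient
data at ≤ 1× coverage sits comfortably inside the linear regime.

At damage rate 0.02 the damage-corrected SE is dominated by the noise of
k̂, which rests on the ~4% of observations in the DU class (DD is nearly
empty); in this world that SE is ~3–4 percentage points and is an
irreducible function of the pair count. Real genome-wide panels carry
many more LD pairs per SNP than the block world at equal SNP counts, and
correspondingly smaller SEs at very low damage rates.

Other limitations: contamination fractions above 0.5 violate the
majority-endogenous assumption and are out of scope; inbreeding is
absorbed only via the negative grid (no explicit runs-of-homozygosity
correction); fully UDG-treated libraries have no damaged fraction, so
only external correction applies; and the estimator treats cross-product
observations as independent, which is why all uncertainty statements
come from the chromosome jackknife rather than the likelihood curvature.
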