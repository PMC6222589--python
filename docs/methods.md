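# Methods

`wgblup` implements a two-step strategy for multi-trait genomic prediction
of a pair of correlated traits, here labelled L (low heritability, 0.1) and
H (high heritability, 0.4):

1. a region-wise Bayesian whole-genome regression estimates a per-SNP
   effect (co)variance that is constant within contiguous genome regions
   and differs between them;
2. those posterior (co)variances weight trait-specific genomic relationship
   matrices, and a multi-trait GBLUP solver predicts breeding values from
   them.

A forward-in-time breeding simulator and a two-trait QTL/phenotype
simulator provide the validation substrate; a replicated experiment driver
compares the Bayesian method, unweighted GBLUP and weighted GBLUP (wGBLUP)
by the correlation between true and estimated breeding values in
descendant test generations.

## Models

### Multi-trait GBLUP and wGBLUP

With phenotypes corrected for everything but the genetic effect and
centered genotypes `X` (dosage − 2p per column), breeding values follow

    [u_L; u_H] ~ N(0, [σ²_uL G      σ_uLH G    ;
                       σ_uLH G      σ²_uH G    ])

in the unweighted model, with `G = XDX′`, `D = I / Σ_j 2 p_j q_j`
(VanRaden method 1).  When each SNP j carries its own (co)variance
(σ²_βL,j, σ²_βH,j, σ_βLH,j), the single G is replaced by the triple

    G_L = X D_L X′,  G_H = X D_H X′,  G_LH = X D_LH X′
    d_L,j = (σ²_βL,j / σ²_βL) / Σ 2pq      (analogously for H and LH)

and the joint genetic covariance uses σ²_uL G_L, σ_uLH G_LH, σ²_uH G_H.
EBVs are the BLUP projection û = Cov(u, y′) Var(y)⁻¹ y, which for animals
without phenotypes is the genomic-covariance projection onto the reference
phenotypes — algebraically identical to solving the mixed-model equations
with missing records, and identical to SNP-BLUP/ridge with per-SNP prior
variance B = vc / Σ2pq (this identity is a test oracle).

Numerical choices: phenotypes are centered by their mean (the fitted mean
is not added back to EBVs); one symmetric (Cholesky) factorization of
(K_rr + R) with a logged jitter of 1e-8·mean(diag) on failure; genetic and
residual 2×2 component matrices are validated and covariances shrunk to
0.999 of the Cauchy–Schwarz bound with a warning when they violate it.

### Region-wise Bayesian sampler

The sampler decomposes the effect of SNP j (region s) on trait t as

    β_tj = r_t · s0_j + r_ts · s1_j + β*_tj

with latent vectors s0, s1 ~ N(0, I) shared across traits, a flat prior on
the genome-wide loading r_t, r_ts ~ N(0, σ²_rt) with a flat positive prior
on σ²_rt, β*_tj ~ N(0, σ²_β*t) with a flat positive prior, and residuals
e ~ N(0, R0 ⊗ I).  Per-SNP posterior moments are accumulated per saved
cycle from the identities var(β_tj) = r_t² + r_ts² + σ²_β*t and
cov(β_Lj, β_Hj) = r_L r_H + r_Ls r_Hs, so the track is exactly constant
within regions.  Trait-level genomic components derive from the track as
σ²_ut = Σ_j 2 p_j q_j var_tj (and the analogous cross sum).

All full conditionals are standard generalized-least-squares forms with
the residual precision W = R0⁻¹ coupling the traits:

- a scalar (or 2-vector) coefficient θ with stacked design columns z_t and
  prior precision P0 has conditional N(Q⁻¹ r, Q⁻¹) with
  Q = Σ_tt′ W_tt′ z_t′z_t′ + P0 and r = Σ_tt′ W_tt′ z_t′ e_t′ (residuals
  with θ's own contribution removed);
- (s0_j, s1_j) are updated jointly per SNP (bivariate normal), as are
  (β*_Lj, β*_Hj), (r_L, r_H) and (r_Ls, r_Hs);
- σ²_rt and σ²_β*t are scaled inverse-χ² draws, df = count − 2 from the
  flat positive prior.  That posterior is proper only beyond two deviates,
  so for chromosome/genome partitions (1–5 regions) the df falls back to
  max(count − 2, 1); a relative floor of 1e-10 of the initial per-SNP
  variance scale keeps draws off exact zero;
- R0 gets a Jeffreys prior |R0|^(−3/2) by default (posterior
  inverse-Wishart(n, E′E)); a proper inverse-Wishart(ν, S) prior is a
  config option.

Update order per cycle: means, β* sweeps, (s0, s1) sweeps, r, region
loadings, variances, R0.  The (r, s) products are sign/scale
non-identifiable; no constraint is imposed because every reported quantity
(r², r·r, var, cov, EBVs) is invariant.  Initialization: μ_t at the
phenotype mean, latent vectors at 0, loadings at 0.01 to break the zero
trap, variances from a phenotypic-variance split.  Residuals are
maintained incrementally and recomputed from scratch every 200 cycles to
kill accumulation drift.  Chains are fully deterministic given the config
seed.  Missing phenotypes are rejected (complete reference records are
assumed).  The per-SNP sweeps are numba-compiled; with the reduced-scale
defaults (495 reference animals, ~1,800 markers, 2,500 cycles) a
two-trait chain runs in roughly 15 s.

The single-trait reduction drops the genome-wide layer
(β_tj = r_ts s1_j + β*_tj) and runs with σ²_β*t fixed at the multi-trait
estimate — by convention the multi-trait run with the same region
partition, since the value is partition-dependent.

Default chain settings are 20,000 cycles, 5,000 burn-in, thinning 10
(1,500 saved samples); the reduced-scale experiments shorten this (below).
Region partitions never span chromosomes (except the single whole-genome
region); the last fixed-k region per chromosome may be short; a k
exceeding the SNP count degrades to one region per chromosome with a
warning.

### Weighted-GRM normalization

Trait-level denominators σ²_βL, σ²_βH, σ_βLH default to the per-SNP means
of the track, which centers the weights at one.  This makes the
uniform-track identity exact (wGBLUP with whole-genome weights reproduces
GBLUP to machine precision) and avoids dividing by a posterior genome-wide
covariance that can be arbitrarily close to zero; supplying an explicit
near-zero covariance denominator with a non-degenerate covariance track is
an error directing the caller back to the default.  Posterior-mean per-SNP
2×2 blocks need not be positive semidefinite, so covariances are clipped
to 0.999·sqrt(var_L·var_H) before GRM construction (count logged).  G_LH
is symmetric but generally indefinite; that is expected and not repaired.
Allele frequencies for centering and Σ2pq come from the pooled
reference+test panel, computed once, so G blocks stay compatible across
generations.

## Simulation

### Population

A base population (G0, the reference) of 2,200 animals — 200 males and
2,000 females, configurable with the 1:10 ratio preserved — is bred
forward: every sire is mated to 10 distinct dams (a random partition of
the females), one offspring per mating, and one mating per sire is
repeated with a fresh meiosis, keeping the census size constant.  Sexes
are reassigned at random each generation in the parental proportions.
Crossover counts per chromosome are Poisson with mean equal to the map
length in Morgans, positions uniform on the genetic map (no interference:
two loci d Morgans apart recombine at the Haldane fraction
(1 − e^(−2d))/2, a test oracle), and there is no mutation and no
selection.  The default genome is five chromosomes of 159/139/127/121/125
Mbp at 1 cM/Mbp, so 1-Mbp windows give 159/139/127/121/125 QTL bins.

The base haplotypes are synthesized per chromosome by a neutral coalescent
with recombination (msprime), effective population size 100 — the order
of magnitude of commercial dairy cattle — with binary mutations at
2e-8/bp.  The panel is then "array-ascertained": for each target map
position the nearby segregating site whose MAF is closest to an
independent Uniform(maf_floor, 0.5) draw is kept.  This reproduces two
features of a genotyping array on livestock data that the method depends
on: a flat common-variant-enriched MAF spectrum (mean SNP MAF ≈ 0.25) and
strong local LD (adjacent-marker r² ≈ 0.18 at the default density,
decaying with distance).  An earlier candidate design — independent-site
founders at uniform frequencies passed through one round of random
mating — was implemented and measured to leave adjacent-marker
correlation indistinguishable from sampling noise (drift LD is O(1/2N)),
which removes the marker–QTL tagging that region-wise weighting exploits;
it was therefore replaced.  What the generator still does *not* emulate:
ascertainment bias correlated with LD, variable recombination along
chromosomes, mutation after the base generation, and selection — so
passing tests support the method's behavior under drift and random
mating, not under selection-driven allele-frequency change.

### Traits

QTL are drawn bin-wise: 1-Mbp bins are visited in random order, a
half-width rw ~ U(0, 0.15) is drawn per bin, and one SNP with MAF in
(0.15 − rw, 0.15 + rw] is chosen uniformly if any qualifies (at most one
QTL per bin; selected SNPs are removed from the marker panel).  Of the
QTL, 82% are pleiotropic; their magnitude pairs are correlated
gamma(0.4, 1.66) variables constructed by a Gaussian copula whose latent
correlation is calibrated by quadrature root-finding so the realized
gamma-pair correlation equals +0.90 (the calibrated latent value is
≈ 0.927).  78% of pleiotropic pairs keep a common sign (one joint random
flip, keeping effects symmetric about zero), the remaining 22% get the
trait-H member's sign flipped.  The remaining 18% of QTL are split evenly
between the traits (ties toward L) with gamma magnitudes and random
signs.  The gamma's second parameter is read as a scale (mean effect
0.4·1.66 = 0.664); a rate reading is a config switch.

This mixture implies a genetic correlation of ≈ 0.46 in the
many-QTL limit (Σ α_L α_H / sqrt(Σ α_L² Σ α_H²) over simulated effect
vectors).  At 200 QTL the *realized* per-replicate correlation is heavy
tailed — a few large gamma products carry much of the genetic covariance
— with a replicate SD near 0.2, so replicate means converge slowly
(≈ 0.445 over 100 replicates); tests and the acceptance script therefore
average enough replicates for the standard error to support the check,
rather than relying on a 10-replicate mean whose SE (~0.065) would exceed
the tolerance being checked.

Phenotypes are y_t = u_t + e_t with residuals drawn independently per
trait, variance var(u_t)·(1 − h²)/h² computed from the empirical TBV
variance of the phenotyped generation (population variance, ddof 0), so
realized heritabilities match the 0.1/0.4 targets in expectation.

## Reduced-scale experiment defaults

Full-scale runs (2,200 animals, 11,154 SNPs, 20,000-cycle chains) are
supported but slow; the experiment driver's defaults are a structurally
faithful reduction chosen once for the package's validation experiments:

- 45 sires × 450 dams (495 animals per generation, 1:10 ratio kept),
  5 generations;
- 2,000 SNPs on the five-chromosome map, 200 QTL;
- multi-trait BayesAS with 100-SNP regions, 2,500 cycles / 500 burn-in /
  thinning 4 (500 saved samples);
- 5 replicates; only G0 phenotypes are used for all test generations
  (a G0+G1 training mode is available via `train_generations`).

Under these conditions the headline pattern of the method reproduces:
mean G1 accuracy of multi-trait wGBLUP exceeds unweighted GBLUP for both
traits and stays within 0.02 of the Bayesian method that supplied the
weights, and GBLUP accuracy declines monotonically from G1 to G5.

## Statistical comparison conventions

Accuracy is the Pearson correlation between true and estimated breeding
values within a test generation; zero-variance inputs yield a missing
value with a warning.  Methods are compared by two-sided paired t-tests
with accuracies paired by replicate within a test population, at 0.05
with Bonferroni correction over the declared family of cell pairs (the
family definition is the caller's; family size is reported alongside each
p-value).  A pair whose replicate differences are all zero is reported as
p = 1 with a degenerate flag rather than NaN.

## Known limitations

- Two traits only; the n-trait generalization (stacked blocks, latent
  vectors shared across all traits) is mechanical but not implemented.
- No REML: variance components always come from the Bayesian run, as in
  the two-step design.
- No missing phenotypes in the reference, no fixed-effect model beyond
  the overall mean (pre-adjust upstream).
- Single-trait runs require a multi-trait run first (for σ²_β*t).
- The sampler's mixing for the genome/chromosome partitions is limited by
  the 1–5 region loadings; posterior variances there are weakly
  identified (df fallback above) though EBVs are stable.
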