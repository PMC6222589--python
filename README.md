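# wgblup — multi-trait weighted GBLUP with Bayesian region weights

Genomic BLUP (GBLUP) assumes every marker carries the same effect
(co)variance, so one relationship matrix **G** serves all traits.  When a
trait pair's genetic architecture violates that — few QTL, regions whose
between-trait covariance deviates from the genome average — Bayesian
whole-genome regression wins, but at much higher computational cost.
`wgblup` implements the two-step alternative for a pair of correlated
traits (L: h² = 0.1, H: h² = 0.4):

1. **Region-wise Bayesian regression** (Gibbs sampler): SNPs within a
   contiguous region (one SNP, k SNPs, a chromosome, or the whole genome)
   share an effect (co)variance; the effect of SNP j in region s on trait
   t is modelled as β_tj = r_t·s0_j + r_ts·s1_j + β*_tj, with latent
   vectors s0, s1 shared across traits carrying the genome-wide and
   region-specific between-trait covariance.  Posterior per-SNP moments
   follow var(β_tj) = r_t² + r_ts² + σ²_β\*t and
   cov(β_Lj, β_Hj) = r_L r_H + r_Ls r_Hs.
2. **Weighted GBLUP**: the posterior (co)variances become diagonal weights
   in trait-specific relationship matrices
   G_L = X D_L X′, G_H = X D_H X′, G_LH = X D_LH X′ with
   d_L,j = (σ²_βL,j / σ²_βL) / Σ2pq (and analogues), and breeding values
   are the BLUP projection û = Cov(u, y′) Var(y)⁻¹ y under

   [u_L; u_H] ~ N(0, [σ²_uL G_L, σ_uLH G_LH; σ_uLH G_LH, σ²_uH G_H]).

   With whole-genome weights this collapses exactly to ordinary GBLUP.

The package is aimed at animal/plant breeding researchers studying
multi-trait genomic prediction.  It ships the full validation substrate:
a coalescent-backed base-panel generator with array-like MAF spectrum and
realistic LD, a forward-in-time breeder (1:10 sire:dam ratio, Poisson
recombination, no mutation), a two-trait QTL simulator (82% pleiotropic
QTL, gamma(0.4, 1.66) effects at pair correlations ±0.90 — emergent
genetic correlation ≈ 0.45), and a replicated experiment driver with
paired-t/Bonferroni comparisons.

## Worked example

Five replicates of the reduced-scale default design — 495 animals per
generation, 2,000 SNPs, 200 QTL, multi-trait BayesAS with 100-SNP regions
feeding GBLUP/wGBLUP, trained on G0 only and scored on G1–G5:

```python
from wgblup import evalx

acc = evalx.run_experiment(evalx.ExperimentConfig(seed=0))
summary = evalx.summarize_accuracy(acc)
g1 = summary[summary.generation == 1].pivot(index="trait",
                                            columns="method",
                                            values="accuracy")
print(g1.round(3))
```

```
method  bayesas  gblup  wgblup
trait
H         0.574  0.543   0.573
L         0.398  0.374   0.393
```

Each number is the mean (over replicates) correlation between true and
estimated breeding values of the first test generation.  The pattern is
the method's point: with 100-SNP-region weights, weighted GBLUP recovers
essentially the full accuracy of the Bayesian method (differences < 0.01)
and beats unweighted GBLUP for both the low- and the high-heritability
trait (+0.019 and +0.030 here).  Accuracies decline from G1 to G5 as the
test animals drift away from the reference (e.g. GBLUP trait H: 0.543 →
0.382), and the decline is slower for the weighted models.

The same pipeline is scriptable from the shell:

```
wgblup simulate --seed 1 --out-dir sim/
wgblup fit-bayesas --phenotypes pheno.tsv --genotypes geno.tsv \
    --region-mode fixed_k --k 100 --cycles 20000 --burn-in 5000 \
    --thin 10 --seed 1 --out-prefix fit
wgblup build-grm --genotypes geno.tsv --weights fit.track.tsv --out g
wgblup predict --grm g --components fit.components.json \
    --phenotypes pheno.tsv --reference-ids ref.txt --method wgblup \
    --out ebv.tsv
wgblup evaluate --config design.yaml --seed 1 --out-dir results/
```

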