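# segment-scan

Region-level analysis of complex traits anchored on a genomic **segment** —
a regulatory element, a region under selection, or an archaic introgressed
haplotype — inside a larger locus. The package is aimed at statistical
geneticists who want to ask, for a segment of interest: how much gene
expression does it control, how much trait heritability does it carry, which
genes mediate its effect on a trait, and how does an archaic genotype
profile compare with modern populations on the expression it predicts?

## What it computes

**Segment-based expression heritability.** Per gene and tissue, a sparse
weighted elastic-net model of residualized expression from cis variant
dosages,

  β̂ = argmin_β ½ Σᵢ wᵢ (gᵢ − xᵢᵀβ)² + λ((1−α)/2‖β‖₂² + α‖β‖₁),  α = 0.5,

where observations stacked across tissues carry weights wᵢ from tissue–
tissue similarity (the cross-tissue model; in-tissue weights 1 and zero
elsewhere gives the single-tissue special case). Five-fold cross-validated
r² between observed and predicted expression estimates the heritability
captured by the model's variant set; a **reduced** model restricted to the
segment versus the **full** cis-wide model gives the concentration
statistic ψ = (h²_red · p_full)/(h²_full · p_red). Random same-length
segments and segment dilation provide the matching null and sensitivity
analyses.

**Local trait heritability from summary statistics.** For a region with p
variants, standardized marginal effects β̂ (z/√n) and LD matrix C,

  r̂²_L = ((β̂ᵀC⁻¹β̂ − q/n)/(n − q))·n,   q = rank(C),

with the Moore–Penrose pseudoinverse when C is singular, a closed-form
sampling variance, and analytic sensitivity of the estimate to LD
perturbations. Because a noisy reference-panel LD matrix inflates the
estimate, the package provides the **projected LD matrix** — the
Ledoit–Wolf shrinkage π(C) = (b²m/d²)I + (a²/d²)Ĉ minimizing expected
Frobenius distance to the true LD matrix — which markedly reduces that
inflation.

**Gene–trait association and phenome scan.** The summary-based weighted-z
statistic z_gene = Σⱼ wⱼσⱼzⱼ / √(wᵀdiag(σ)C diag(σ)w) with
Benjamini–Hochberg FDR, and a phenome-scan driver that selects genes by the
reduced model's imputability (cv r > 0.1, P < 0.05) and tests with full
models on traits with ≥ 50 cases.

**Penalized Mendelian randomization.** The joint estimator

  argmin_{u,v,w} Σⱼ (θ̂ⱼ − uβ̂ⱼ − vⱼ − w lⱼ)² + λ(‖v‖₁ + |u| + |w|)

of the gene causal effect u, per-instrument heterogeneity vⱼ (horizontal
pleiotropy/confounding) and LD-score effect w, with palindromic-IV removal,
greedy clumping (p < 0.05, r² < 0.1), CV-selected λ, a relaxed (OLS on
support, robustly re-selected) refit, and a percentile bootstrap CI; plus
the IVW baseline.

**Mediation share and GDE-scores.** The decomposition θ̂ = α̂β̂ + ĥ, the
segment share of expression-mediated effect π_c (a ratio of rank-corrected
quadratic forms under projected LD), its per-SNP concentration ψ_e, and
genetically determined expression (GDE) scores over genotype panels,
including archaic profiles with the ≥ 2-genotyped-predictor rule.

All fixtures are generated by the `simulate` module (Gaussian-copula
genotypes under HWE with block-AR(1) LD); nothing needs downloading.

## Worked example

```python
import numpy as np
import segment_scan as ss

seg = ss.parse_segment("chr3:45,859,651-45,909,024")
print(len(seg))                 # 49374  (a ~49.4 kb segment)

# two SNPs, rho = 0.5, standardized effects 0.1 at n = 1000
est, d = ss.two_snp_closed_forms(0.1, 0.1, 0.5, 1000)
print(round(est, 6), round(d, 6))   # 0.008016 -0.02004

# projected LD from a simulated 500-subject panel
panel = ss.simulate_genotypes(
    500, target_ld=ss.ar1_block_ld(150, np.random.default_rng(1)), seed=2)
proj = ss.ledoit_wolf_project(panel)
print(round(proj.shrinkage, 3))     # 0.22  (weight on the identity target)

# local heritability of a simulated region, three LD modes
cfg = ss.SimConfig(n_reps=20, h2_levels=(0.02,), seed=3)
print(ss.summarize_local_h2_study(ss.simulate_local_h2_study(cfg))
      [["ld_mode", "mean", "mc_se"]])
#      ld_mode      mean     mc_se
# 0   observed  0.030409  0.000483
# 1  projected  0.024598  0.000311
# 2       true  0.020228  0.000234
```

The last block shows the point of the projection: with the raw 500-subject
panel LD the region's heritability (true value 0.02) is overestimated by
~50%; the projected matrix removes most of that inflation; the in-sample
("true") LD recovers the generating value.

A command-line interface mirrors the library:
`segment-scan {train, project-ld, h2, assoc, mr, pi-c, gde, phewas, simulate}`;
every run writes a `manifest.json` sufficient to reproduce it.

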