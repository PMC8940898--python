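# Methods

This note documents the models implemented in `segment_scan`, the design
choices made where the methodology left room, and what the bundled
simulations do and do not establish.

## Coordinates, variants, and harmonization

Coordinates are 0-based half-open internally; all text I/O is 1-based
inclusive (`chr3:45,859,651-45,909,024`). Variant identity is keyed on
(chrom, pos, sorted allele pair), which survives rsID divergence between
panels; multi-allelic sites are dropped on input. When aligning an eQTL or
model record to a GWAS record, matching effect/other alleles pass through,
swapped alleles flip the GWAS sign, and palindromic (A/T, C/G) variants are
dropped wherever strand cannot be assumed — always for MR instruments.
Missing dosages are mean-imputed per variant; training uses common variants
(MAF ≥ 0.05, inclusive).

## Expression models and segment heritability

A gene's model is a weighted elastic net (mixing α = 0.5; the L1 part
matches the sparse architecture of expression regulation, the L2 part
groups correlated variants) over observations stacked across tissues.
Observation weights for test tissue t and source tissue s default to
`expression_similarity[t,s]^h1 * regulatory_similarity[t,s]^h2`, with
(h1, h2) tuned on the grid {0, 1, 2, 4, ∞} by cross-validated r² (∞
hard-thresholds to the test tissue alone, the single-tissue special case);
a user-supplied weight map bypasses tuning. λ is chosen by 5-fold CV with
the one-standard-error rule on a 25-point geometric grid from the smallest
all-zero-coefficient λ. CV folds are grouped by donor so no donor spans
train and test — donor leakage would inflate the performance estimate.
Coefficients are fit by scikit-learn's coordinate descent with per-sample
weights.

Cross-validated r² (squared Pearson correlation of held-out observed vs
predicted expression) estimates the expression heritability attributable to
the model's variant set; zero-variance predictions score r = 0, p = 1
rather than NaN. The imputable-gene rule is r > 0.1 and P < 0.05, both
strict. Reduced models restrict features to a segment; the concentration
statistic ψ compares per-SNP heritability between reduced and full models.
The random-segment null places same-length segments uniformly within the
gene's cis window (rejecting placements with < 2 post-filter variants) and
compares observed vs per-gene null-median r² by a two-sided Wilcoxon
signed-rank test across genes; the test is reported as p = 1 when all
paired differences vanish (statistic undefined at its null center).

## LD matrices and the Ledoit–Wolf projection

Empirical LD is the Pearson correlation of dosage columns (ddof 0, so
Ĉ = XᵀX/n for standardized X). The projected matrix is

    π(C) = (b²m/d²) I + (a²/d²) Ĉ,
    m = ⟨Ĉ, I⟩,  d² = ‖Ĉ − mI‖²,
    b² = min(d², n⁻²Σₖ‖XₖXₖᵀ − Ĉ‖²),  a² = d² − b²,

with all Frobenius products normalized by p so that m is the mean diagonal
(1 on the correlation scale) and the four scalars share one scale; the
alternative reading of d as a norm rather than a squared norm makes the
shrinkage weights dimensionally inconsistent, so the squared-norm
convention is used. The per-subject sum is evaluated in closed form
(Σₖ(XₖᵀXₖ)²/p − n·tr(Ĉ²)/p), avoiding the p×p outer products. When
d² ≈ 0 the observed matrix is returned unshrunk. The implementation is
cross-checked in the tests against scikit-learn's independent Ledoit–Wolf
estimator on pre-standardized data.

Inverses use an eigendecomposition with singular values below 1e-8 of the
largest treated as zero (float64 noise floor for p up to a few thousand);
the effective rank q is the number retained.

## Local heritability and its LD sensitivity

The estimator consumes standardized marginal effects β̂ = z/√n. The
rank-adjusted form (q = rank(C) replacing the variant count p in both the
point estimate and the variance) is the default because reference-panel
matrices are routinely rank-deficient; the unadjusted form is available via
a flag. Negative estimates are reported as-is — flooring at zero would bias
simulation means. The two-SNP closed forms are implemented exactly as the
divisor-free printed expressions (estimate, derivative in ρ, and the
singular ρ = 1 branch, which agrees with the pseudoinverse route of the
general estimator). The LD-sensitivity report gives entry (i,j) as
β̂ᵢβ̂ⱼ·n/(n−q), the derivative of the estimator's quadratic form under a
one-to-one perturbation of the single matrix entry; tests pin this
convention to a central finite difference.

## Gene–trait association

The weighted-z statistic uses dosage SDs implied by allele frequency under
Hardy–Weinberg, σⱼ = √(2fⱼ(1−fⱼ)), and the predictor LD matrix (identity
when omitted). It is validated by its null calibration — standard normal
under iid null z for arbitrary fixed weights — rather than against any
external constant. BH FDR is applied within each scan by default (the
joint gene×tissue set); phenome scans exclude traits with fewer than 50
cases and test full models for genes whose reduced model is imputable in at
least one tissue.

## Penalized MR

The objective regresses instrument-level GWAS effects on eQTL effects with
a per-instrument heterogeneity term and an LD-score term, all under a
uniform L1 penalty. Two implementation points matter:

- **Column standardization.** The solver standardizes the design columns
  (as glmnet does) before penalizing. Without this, whenever Σⱼ|β̂ⱼ| ≲ 1 —
  the typical situation for raw eQTL effect sizes — the KKT conditions
  never activate the causal term and the estimator degenerates to α̂ = 0
  with the heterogeneity terms absorbing everything.
- **Relaxed refit with robust re-selection.** The penalized point estimate
  of the causal effect is shrunken by construction (the |u| penalty trades
  directly against ‖v‖₁). The relaxed estimate refits OLS on the selected
  support and then iterates one robust re-selection to a fixed point:
  instruments whose residuals against the current (u, w) fit exceed 3
  robust SDs (1.4826·MAD) are flagged as heterogeneous and excluded from
  the refit. The iteration exists because the penalized fit's shrunken u
  distorts the residuals the initial selection sees, leaving a ~1–2%
  upward leak from under-flagged invalid instruments; at the fixed point
  the recovery simulations are unbiased to within Monte-Carlo error.

λ is selected by 5-fold CV over instruments on the relaxed fit's held-out
predictions (u·β̂ + w·l; held-out heterogeneity terms are unidentified and
predicted as zero) with a one-SE rule toward the sparse end, since the CV
curve is flat near its minimum and the refit needs a sparse support.
Inference is a percentile bootstrap over instruments at the selected λ,
widened if necessary to contain the point estimate; multiplicity is left to
the caller. Clumping is greedy: sort by eQTL p (ties by genomic position),
keep iff p < 0.05 and r² < 0.1 against all kept; residual IV–IV correlation
is retained and reported.

## Mediation share and GDE-scores

π_c is the ratio of rank-corrected mediated-effect quadratic forms under
projected LD (raw Ĉ available behind a flag), reported unclipped with a
flag outside [0, 1]; with α̂ = 0 or a non-positive denominator the value
carries no mediation signal and is flagged degenerate rather than defined
away. ψ_e = π_c·q_full/q_reduced is this package's construction, mirroring
ψ's per-SNP normalization using effective ranks. GDE-scores are the dot
product of model weights with subject dosages; predictors missing from a
profile contribute zero (no imputation — archaic missingness is
structural), and archaic scores require ≥ 2 genotyped predictors. Archaic
placement is the empirical quantile of the archaic score within each
population's score distribution.

## Synthetic data

Genotypes are Gaussian-copula draws: latent N(0, R) thresholded per variant
at the Hardy–Weinberg genotype-frequency quantiles of its allele frequency
(MAFs U(0.05, 0.5) unless given). The default LD template is block-AR(1)
with per-block ρ ~ U(0.2, 0.9) — a stand-in for empirically derived
segment LD; an empirical matrix can be passed instead. Discretization
attenuates dosage-scale correlation mildly relative to the latent target
(all estimators and "truth" matrices are computed on the dosage scale, so
the comparison is internally consistent).

The **local-heritability study** uses one causal variant per replicate,
Y = βG + ε with β = √h², trait variance 1, n = 50,000 per cohort, a 150
variant / 50 kb segment (the variant count is this package's choice;
configurable), and an independent 500-subject panel for Ĉ and π(C);
marginal effects are per-variant OLS on standardized dosages. The **MR
study** simulates per gene 20 independent instruments, eQTL effects
Gaussian with total expression h² = 0.10 (a median-gene architecture),
residual variance σ²_X = var(βG)(1−h²)/h², trait Y = αX + Z + ε_Y with 20%
of instruments invalid and pleiotropic effects twice their mediated effect
(2αβⱼ); both marginal effect sets are estimated from the simulated cohort.
Test and acceptance runs use ~100 replicates/genes; the paper-scale default
in `SimConfig` is 500.

## What the simulations show — and don't

- With the generating ("true") LD the local estimator is unbiased to within
  Monte-Carlo error at h² ∈ {0.01, 0.02, 0.03} (means 0.0100/0.0203/0.0300
  over 100 replicates).
- With the raw 500-subject panel LD it overestimates substantially (~1.5×
  at h² = 0.01); the projection removes most, but not all, of the inflation
  (~1.2×, e.g. mean 0.0122 at h² = 0.01). The residual is structural:
  inverting any noisy or shrunken LD proxy inflates the single-causal
  quadratic form ((CM⁻¹C)ᵢᵢ > 1 for M ≠ C), so the projected mean does not
  coincide with the truth at this panel size and variant density — the
  correct reading is "much less biased", not "unbiased". The corresponding
  strict recovery assertion in `tests/test_acceptance.py` is expected to
  fail and is retained as an honest record of this limit.
- The penalized MR estimator (relaxed, refined) recovers α at 0, 0.3 and
  0.5 to within Monte-Carlo error over 100 genes, while IVW is biased
  upward by ≈ 2·invalid-fraction·α, matching theory.
- Synthetic panels have block LD, exact HWE, no population structure, no
  genotyping error, and exchangeable samples; passing these studies says
  the estimators are correct under their own assumptions, not that real
  cohorts meet those assumptions.

## Numerical conventions

Elastic-net solver tolerance 1e-7 (coefficient agreement between the
cross-tissue special case and the single-tissue fit is asserted to 1e-6);
pseudoinverse cutoff 1e-8 of the largest singular value; copula jitter
1e-10 on the template diagonal before Cholesky; all randomness flows from
user-supplied integer seeds through `numpy.random.default_rng`, with
per-replicate substreams drawn below 2³¹.
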