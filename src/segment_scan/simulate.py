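"""Synthetic genotype, expression, and summary-statistics generators, plus
the two calibration studies (local heritability and MR parameter recovery).

Genotypes are drawn by a Gaussian copula: latent multivariate normal
vectors with a target correlation are thresholded per variant into {0,1,2}
dosages at the Hardy-Weinberg genotype frequencies of its allele
frequency. The default LD template is a block AR(1) correlation (block
rho ~ U(0.2, 0.9)) standing in for empirically derived segment LD; an
empirical correlation matrix can be supplied instead.

The local-heritability study draws a trait Y = beta G + eps with one
causal variant explaining a set fraction of variance, computes per-variant
marginal effects in a GWAS-sized cohort, and re-estimates the segment
heritability with the true, observed-panel, and projected-panel LD
matrices. The MR study simulates expression X = beta G + eps_X and trait
Y = alpha X + Z + eps_Y with a fifth of instruments carrying a pleiotropic
effect twice their mediated effect, then compares IVW with the penalized
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, GenotypeMatrix, Variant
from .heritability import estimate_local_h2
from .ld import empirical_ld, ledoit_wolf_project, ld_scores
from .mr import IVSet, Instrument, ivw, mr_jti


@dataclass
class SimConfig:
    """Study-design parameters for the two calibration studies."""

    n_gwas: int = 50_000
    n_panel: int = 500
    n_reps: int = 500
    h2_levels: tuple[float, ...] = (0.01, 0.02, 0.03)
    alpha_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    invalid_frac: float = 0.2
    pleiotropy_ratio: float = 2.0
    segment_bp: int = 50_000
    n_variants: int = 150
    n_genes: int = 100
    n_iv_per_gene: int = 20
    seed: int = 0


def ar1_block_ld(
    p: int,
    rng: np.random.Generator,
    block_size: int = 25,
    rho_range: tuple[float, float] = (0.2, 0.9),
) -> np.ndarray:
    """Block-diagonal AR(1) correlation template for a simulated segment."""
    C = np.eye(p)
    start = 0
    while start < p:
        stop = min(start + block_size, p)
        rho = rng.uniform(*rho_range)
        idx = np.arange(start, stop)
        C[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
        start = stop
    return C


def simulate_genotypes(
    n: int,
    target_ld: np.ndarray | None = None,
    mafs: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    chrom: str = "chrS",
    start_pos: int = 1_000_000,
    spacing: int = 330,
) -> GenotypeMatrix:
    """Gaussian-copula dosages matching target LD and allele frequencies.

    Latent N(0, R) draws are cut per variant at the HWE genotype-frequency
    quantiles of its allele frequency; discretization attenuates the
    dosage-scale correlation slightly relative to the latent target.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n <= 0:
        raise ValueError("n must be positive")
    if target_ld is None and mafs is None:
        raise ValueError("supply target_ld and/or mafs")
    if target_ld is not None:
        R = np.asarray(target_ld, dtype=float)
        p = R.shape[0]
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-8:
            raise ValueError("target LD matrix is not positive semidefinite")
    else:
        p = len(mafs)
        R = np.eye(p)
    if mafs is None:
        mafs = rng.uniform(0.05, 0.5, size=p)
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("mafs must lie in (0, 0.5]")

    L = np.linalg.cholesky(R + 1e-10 * np.eye(p))
    z = rng.standard_normal((n, p)) @ L.T
    # HWE cutpoints: P(0)=(1-f)^2, P(1)=2f(1-f), P(2)=f^2 for alt freq f
    f = mafs
    c0 = stats.norm.ppf((1 - f) ** 2)
    c1 = stats.norm.ppf((1 - f) ** 2 + 2 * f * (1 - f))
    dosages = (z > c0).astype(float) + (z > c1)

    variants = [
        Variant(
            id=f"snp{j}", chrom=chrom, pos=start_pos + j * spacing,
            ref_allele="A", alt_allele="G",
            maf=float(min(mafs[j], 1 - mafs[j])),
        )
        for j in range(p)
    ]
    samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def _marginal_std_effects(x_std: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-variant marginal OLS effects on the standardized (per-SD) scale."""
    y_std = (y - y.mean()) / y.std()
    return x_std.T @ y_std / len(y)


def simulate_local_h2_study(config: SimConfig) -> pd.DataFrame:
    """Single-causal-variant recovery study for the local h2 estimator.

    Per replicate: draw a fresh LD template and GWAS cohort, pick one
    causal variant, form Y = beta G + eps with var explained h2, compute
    standardized marginal effects, and estimate local h2 with the true LD,
    the observed 500-subject panel LD, and its projection. Returns the
    long table (rep, h2_true, ld_mode, h2_hat, variance).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(config.n_reps):
        rep_rng = np.random.default_rng(rng.integers(2**31 - 1))
        template = ar1_block_ld(config.n_variants, rep_rng)
        mafs = rep_rng.uniform(0.05, 0.5, size=config.n_variants)
        geno = simulate_genotypes(
            config.n_gwas, target_ld=template, mafs=mafs, seed=rep_rng,
            spacing=max(config.segment_bp // config.n_variants, 1),
        )
        x_std = geno.standardized()
        true_ld = (x_std.T @ x_std) / config.n_gwas  # in-sample LD of the cohort
        panel = simulate_genotypes(
            config.n_panel, target_ld=template, mafs=mafs, seed=rep_rng,
        )
        proj = ledoit_wolf_project(panel)
        causal = int(rep_rng.integers(config.n_variants))
        g = x_std[:, causal]
        for h2 in config.h2_levels:
            beta = np.sqrt(h2)  # G standardized, var(Y)=1
            eps = rep_rng.standard_normal(config.n_gwas) * np.sqrt(1.0 - h2)
            y = beta * g + eps
            beta_std = _marginal_std_effects(x_std, y)
            for mode, C in (
                ("true", true_ld),
                ("observed", proj.base.C_hat),
                ("projected", proj.pi_C),
            ):
                est = estimate_local_h2(beta_std, C, config.n_gwas, ld_mode=mode)
                rows.append(
                    {"rep": rep, "h2_true": h2, "ld_mode": mode,
                     "h2_hat": est.r2_local, "variance": est.variance,
                     "q_rank": est.q_rank}
                )
    return pd.DataFrame(rows)


def summarize_local_h2_study(table: pd.DataFrame) -> pd.DataFrame:
    """Mean estimate, bias, and Monte-Carlo SE per (h2_true, ld_mode)."""
    out = (
        table.groupby(["h2_true", "ld_mode"])["h2_hat"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    out["mc_se"] = out["std"] / np.sqrt(out["count"])
    out["bias"] = out["mean"] - out["h2_true"]
    return out


def simulate_mr_study(
    config: SimConfig,
    alpha_levels: tuple[float, ...] | None = None,
    n_boot: int = 0,
) -> pd.DataFrame:
    """Parameter-recovery study comparing IVW with the penalized estimator.

    Per gene: independent instruments with eQTL effects drawn from a
    Gaussian scaled so the instruments explain ~10% of expression variance
    (median-gene architecture); expression X = beta G + eps_X; trait
    Y = alpha X + Z + eps_Y where the designated invalid fraction of
    instruments carries a direct (pleiotropic) effect equal to
    ``pleiotropy_ratio`` times its mediated effect alpha*beta_j. Marginal
    eQTL and GWAS effects are then estimated by per-variant OLS and passed
    to both estimators.
    """
    alpha_levels = alpha_levels if alpha_levels is not None else config.alpha_grid
    rng = np.random.default_rng(config.seed)
    J = config.n_iv_per_gene
    n_invalid = int(round(config.invalid_frac * J))
    h2_x = 0.10
    rows = []
    for gene in range(config.n_genes):
        gene_rng = np.random.default_rng(rng.integers(2**31 - 1))
        mafs = gene_rng.uniform(0.05, 0.5, size=J)
        geno = simulate_genotypes(config.n_gwas, mafs=mafs, seed=gene_rng)
        x_std = geno.standardized()
        beta = gene_rng.standard_normal(J) * np.sqrt(h2_x / J)
        genetic = x_std @ beta
        sigma_x2 = np.var(genetic) * (1.0 - h2_x) / h2_x
        invalid = gene_rng.choice(J, size=n_invalid, replace=False)
        iv_ld = empirical_ld(geno).C_hat
        l_scores = ld_scores(iv_ld)
        for alpha in alpha_levels:
            X = genetic + gene_rng.standard_normal(config.n_gwas) * np.sqrt(sigma_x2)
            Z = x_std[:, invalid] @ (config.pleiotropy_ratio * alpha * beta[invalid])
            Y = alpha * X + Z + gene_rng.standard_normal(config.n_gwas)

            beta_hat = _ols_marginals(x_std, X)
            theta_hat, theta_se = _ols_marginals(x_std, Y, with_se=True)
            beta_se = np.full(J, np.std(X) / np.sqrt(config.n_gwas))
            instruments = [
                Instrument(
                    variant=geno.variants[j].id, chrom=geno.variants[j].chrom,
                    pos=geno.variants[j].pos, effect_allele="G", other_allele="A",
                    beta_exposure=beta_hat[j], se_exposure=beta_se[j],
                    p_exposure=2 * stats.norm.sf(abs(beta_hat[j] / beta_se[j])),
                    beta_outcome=theta_hat[j], se_outcome=theta_se[j],
                    ld_score=l_scores[j],
                )
                for j in range(J)
            ]
            iv_set = IVSet(instruments=instruments, ld=iv_ld)
            a_ivw, _ = ivw(iv_set)
            fit = mr_jti(iv_set, n_boot=n_boot,
                         seed=int(gene_rng.integers(2**31 - 1)))
            rows.append(
                {"gene": gene, "alpha_true": alpha, "alpha_ivw": a_ivw,
                 "alpha_mrjti": fit.alpha_hat,
                 "alpha_mrjti_penalized": fit.alpha_penalized,
                 "n_invalid": n_invalid}
            )
    return pd.DataFrame(rows)


def _ols_marginals(
    x_std: np.ndarray, y: np.ndarray, with_se: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Per-variant simple OLS slopes of y on each standardized column."""
    n = len(y)
    yc = y - y.mean()
    slopes = x_std.T @ yc / n
    if not with_se:
        return slopes
    # residual variance per marginal regression
    resid_var = np.maximum(np.var(yc) - slopes**2, 1e-12)
    return slopes, np.sqrt(resid_var / n)


def simulate_multitissue_expression(
    n_tissues: int,
    n_samples: int | list[int],
    similarity: float,
    h2_expr: float,
    n_causal: int,
    n_variants: int = 30,
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict[str, ExpressionMatrix], dict]:
    """Genotypes plus per-tissue expression with cross-tissue effect
    correlation ``similarity`` and per-tissue heritability ``h2_expr``.

    Returns (genotypes, {tissue: ExpressionMatrix}, truth record with the
    causal variants and per-tissue genetic components). Tissues share the
    donor panel; each tissue measures its first ``n_samples[t]`` donors.
    """
    if not 0.0 <= similarity <= 1.0:
        raise ValueError("similarity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(n_samples, int):
        n_samples = [n_samples] * n_tissues
    n_total = max(n_samples)
    template = ar1_block_ld(n_variants, rng, block_size=10)
    geno = simulate_genotypes(n_total, target_ld=template, seed=rng)
    x_std = geno.standardized()
    causal = rng.choice(n_variants, size=n_causal, replace=False)

    base = rng.standard_normal(n_causal)
    tissues = {}
    truth = {"causal_variants": [geno.variants[j].id for j in causal],
             "genetic_components": {}}
    for t in range(n_tissues):
        tname = f"tissue{t}"
        specific = rng.standard_normal(n_causal)
        eff = np.sqrt(similarity) * base + np.sqrt(1 - similarity) * specific
        eff *= np.sqrt(h2_expr / n_causal)
        genetic = x_std[:, causal] @ eff
        scale = np.std(genetic)
        if scale > 0:  # normalize so genetic variance is exactly h2_expr
            genetic = genetic / scale * np.sqrt(h2_expr)
        noise = rng.standard_normal(n_total) * np.sqrt(1.0 - h2_expr)
        expr = genetic + noise
        samples = geno.samples[: n_samples[t]]
        tissues[tname] = ExpressionMatrix(
            tissue=tname,
            values=pd.DataFrame([expr[: n_samples[t]]], index=["gene1"],
                                columns=samples),
        )
        truth["genetic_components"][tname] = genetic
    return geno, tissues, truth
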