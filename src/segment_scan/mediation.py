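"""Expression-mediated effect decomposition, the segment share pi_c, and
genetically determined expression (GDE) scores.

A variant's GWAS marginal effect decomposes into the component mediated by
a gene's expression and an indirect remainder:

    theta_hat = alpha_hat * beta_hat + h_hat

with alpha_hat the MR causal effect of the gene and beta_hat the eQTL
effect. Replacing theta by the mediated vector alpha*beta in the local
heritability quadratic form for the reduced (segment-only) and full
(cis-wide) predictor sets gives the proportion of expression-mediated
causal effect explained by the segment:

    pi_c = (alpha^2 b_r' C*_r b_r - q_r/n) / (alpha^2 b_f' C*_f b_f - q_f/n)
           * (n - q_f) / (n - q_r)

where C* are projected (Ledoit-Wolf) LD matrices and q their ranks.

The GDE-score applies a gene's model weights to a subject's dosages. For
archaic genotype profiles the score is reported only when at least two of
the model's predictor SNPs are genotyped; missing predictors contribute
zero (archaic missingness is structural, not random, so mean imputation
would be misleading).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .ld import matrix_rank_svd
from .models import ExpressionModel

MODERN_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")


def mediated_decomposition(
    theta_hat: np.ndarray, alpha_hat: float, beta_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split GWAS effects into mediated (alpha*beta) and indirect parts."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    beta_hat = np.asarray(beta_hat, dtype=float)
    if theta_hat.shape != beta_hat.shape:
        raise ValueError("theta and beta must have equal length")
    mediated = alpha_hat * beta_hat
    return mediated, theta_hat - mediated


@dataclass
class MediationResult:
    pi_c: float
    alpha_hat: float
    q_full: int
    q_reduced: int
    n: int
    psi_e: float
    out_of_range_flag: bool
    degenerate: bool = False
    indirect_effect: np.ndarray | None = None


def pi_c(
    alpha_hat: float,
    beta_full: np.ndarray,
    beta_reduced: np.ndarray,
    C_full_proj: np.ndarray,
    C_reduced_proj: np.ndarray,
    n: int,
    *,
    theta_full: np.ndarray | None = None,
) -> MediationResult:
    """Proportion of expression-mediated causal effect explained by the
    segment.

    ``beta_reduced`` are the eQTL effects of the segment (reduced-model)
    predictors, a subset of ``beta_full``; the C* arguments are the
    corresponding projected LD matrices. Values are reported unclipped with
    ``out_of_range_flag`` set outside [0, 1]. With alpha = 0 (or a
    non-positive denominator) the ratio carries no mediation signal and the
    result is flagged degenerate.

    ``psi_e`` rescales pi_c by q_full/q_reduced: the per-SNP concentration
    of the expression-mediated effect in the segment, the mediated analog
    of the heritability concentration statistic.
    """
    beta_full = np.asarray(beta_full, dtype=float)
    beta_reduced = np.asarray(beta_reduced, dtype=float)
    C_full_proj = np.asarray(C_full_proj, dtype=float)
    C_reduced_proj = np.asarray(C_reduced_proj, dtype=float)
    if len(beta_reduced) > len(beta_full):
        raise ValueError("reduced predictor set larger than full set")
    if n <= max(C_full_proj.shape[0], C_reduced_proj.shape[0]):
        raise ValueError("n must exceed both LD ranks")
    q_full = matrix_rank_svd(C_full_proj)
    q_red = matrix_rank_svd(C_reduced_proj)
    num = alpha_hat**2 * (beta_reduced @ C_reduced_proj @ beta_reduced) - q_red / n
    den = alpha_hat**2 * (beta_full @ C_full_proj @ beta_full) - q_full / n
    correction = (n - q_full) / (n - q_red)
    degenerate = den <= 0 or alpha_hat == 0.0
    value = float(num / den * correction) if den != 0 else float("nan")
    indirect = None
    if theta_full is not None:
        _, indirect = mediated_decomposition(theta_full, alpha_hat, beta_full)
    psi_e = value * q_full / q_red if np.isfinite(value) and q_red > 0 else float("nan")
    return MediationResult(
        pi_c=value,
        alpha_hat=alpha_hat,
        q_full=q_full,
        q_reduced=q_red,
        n=n,
        psi_e=float(psi_e),
        out_of_range_flag=not (np.isfinite(value) and 0.0 <= value <= 1.0),
        degenerate=bool(degenerate),
        indirect_effect=indirect,
    )


@dataclass
class GDEScore:
    subject: str
    gene: str
    tissue: str
    score: float
    n_predictors_used: int
    population_label: str = ""
    suppressed: bool = False
    reason: str = ""


def gde_score(
    model: ExpressionModel,
    dosages: dict[str, float],
    *,
    subject: str = "",
    population_label: str = "",
    min_predictors: int = 1,
) -> GDEScore:
    """Genetically determined expression score for one subject.

    ``dosages`` maps variant id to dosage; predictors absent from the map
    contribute zero. Scores based on fewer than ``min_predictors``
    genotyped predictors (default 2 for archaic profiles) are suppressed.
    """
    used = [vid for vid in model.weights if vid in dosages]
    if len(used) < min_predictors:
        return GDEScore(
            subject=subject, gene=model.gene, tissue=model.tissue,
            score=float("nan"), n_predictors_used=len(used),
            population_label=population_label, suppressed=True,
            reason=f"only {len(used)} of {len(model.weights)} predictors "
                   f"genotyped (need >= {min_predictors})",
        )
    score = float(sum(model.weights[v] * dosages[v] for v in used))
    return GDEScore(
        subject=subject, gene=model.gene, tissue=model.tissue, score=score,
        n_predictors_used=len(used), population_label=population_label,
    )


ARCHAIC_MIN_PREDICTORS = 2


def population_gde_distributions(
    model: ExpressionModel,
    panel: GenotypeMatrix,
    population_labels: dict[str, str],
    archaic_dosages: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float] | None, GDEScore | None]:
    """Per-population GDE-score summaries and the archaic score's placement.

    Returns (summary table, archaic empirical quantile per population,
    archaic score). The archaic score obeys the >= 2-genotyped-predictor
    rule; when suppressed the quantiles are None.
    """
    pops = sorted(set(population_labels.values()))
    if archaic_dosages is None and len(pops) < 2:
        raise ValueError("need >= 2 populations or an archaic profile")
    by_id = {v.id: j for j, v in enumerate(panel.variants)}
    scores = {}
    for i, s in enumerate(panel.samples):
        dos = {vid: panel.dosages[i, by_id[vid]] for vid in model.weights
               if vid in by_id}
        scores[s] = gde_score(model, dos, subject=s,
                              population_label=population_labels.get(s, ""))
    rows = []
    per_pop: dict[str, np.ndarray] = {}
    for pop in pops:
        vals = np.array([scores[s].score for s in panel.samples
                         if population_labels.get(s) == pop])
        per_pop[pop] = vals
        rows.append({
            "population": pop, "n": len(vals), "mean": vals.mean(),
            "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
            "q05": np.quantile(vals, 0.05), "median": np.median(vals),
            "q95": np.quantile(vals, 0.95),
        })
    summary = pd.DataFrame(rows)
    archaic = None
    quantiles = None
    if archaic_dosages is not None:
        archaic = gde_score(
            model, archaic_dosages, subject="archaic",
            population_label="archaic",
            min_predictors=ARCHAIC_MIN_PREDICTORS,
        )
        if not archaic.suppressed:
            quantiles = {
                pop: float(np.mean(vals <= archaic.score))
                for pop, vals in per_pop.items()
            }
    return summary, quantiles, archaic
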