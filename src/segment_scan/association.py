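"""Gene-trait association from GWAS summary statistics and model weights.

The gene-level statistic is the standard summary-based weighted z:

    z_gene = sum_j w_j sigma_j z_j / sigma_g,
    sigma_g = sqrt(w' diag(sigma) C diag(sigma) w)

with w_j the model weight of predictor j, sigma_j the dosage SD implied by
its allele frequency under Hardy-Weinberg (sqrt(2 f (1 - f))), z_j the GWAS
z-score harmonized to the model's effect allele, and C the predictor LD
matrix. Under the null of no association z_gene is standard normal for any
fixed weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GwasSummary
from .models import ExpressionModel, igene_filter


@dataclass
class GeneAssociation:
    gene: str
    tissue: str
    trait: str
    z: float
    p: float
    n_snps_used: int
    p_fdr: float = float("nan")


def hwe_dosage_sd(maf: float) -> float:
    """Dosage standard deviation implied by allele frequency under HWE."""
    return float(np.sqrt(2.0 * maf * (1.0 - maf)))


def gene_trait_association(
    model: ExpressionModel,
    gwas: GwasSummary,
    ld: np.ndarray | None = None,
    *,
    drop_palindromic: bool = False,
) -> GeneAssociation:
    """Weighted-z gene-trait association for one model and one trait.

    GWAS records are matched to model predictors on (chrom, pos, allele
    pair) and sign-harmonized to the model's effect (alt) allele. ``ld`` is
    the predictor-predictor correlation matrix in model predictor order;
    identity is assumed when omitted. Palindromic predictors are kept by
    default (model and GWAS assumed strand-consistent); enable
    ``drop_palindromic`` when they are not.
    """
    if not model.weights:
        raise ValueError("model has no predictors")
    idx = gwas.lookup()
    weights, sds, zs, kept = [], [], [], []
    for k, var in enumerate(model.predictor_variants):
        row = idx.get(var.key)
        if row is None:
            continue
        rec = gwas.table.iloc[row]
        if var.is_palindromic and drop_palindromic:
            continue
        # orient by stated allele labels (sources assumed strand-consistent)
        if (var.alt_allele, var.ref_allele) == (rec["ea"], rec["oa"]):
            z_j = float(rec["z"])
        elif (var.alt_allele, var.ref_allele) == (rec["oa"], rec["ea"]):
            z_j = -float(rec["z"])
        else:
            continue  # irreconcilable allele pair
        weights.append(model.weights[var.id])
        sds.append(hwe_dosage_sd(var.maf))
        zs.append(z_j)
        kept.append(k)
    if not kept:
        raise ValueError("no overlapping predictors between model and GWAS")
    w = np.asarray(weights) * np.asarray(sds)
    z_vec = np.asarray(zs)
    if ld is None:
        C = np.eye(len(kept))
    else:
        C = np.asarray(ld, dtype=float)[np.ix_(kept, kept)]
    sigma_g2 = float(w @ C @ w)
    if sigma_g2 <= 0:
        raise ValueError("zero predicted-expression variance")
    z_gene = float(w @ z_vec / np.sqrt(sigma_g2))
    p = float(2.0 * stats.norm.sf(abs(z_gene)))
    return GeneAssociation(
        gene=model.gene, tissue=model.tissue, trait=gwas.trait,
        z=z_gene, p=max(p, np.finfo(float).tiny), n_snps_used=len(kept),
    )


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, pass flags)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvalues <= 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    # flag on the adjusted values so flags and p_fdr stay consistent
    return p_adj, p_adj < q


@dataclass
class TraitEntry:
    """A phenome-scan trait: its summary statistics and case count."""

    trait: str
    gwas: GwasSummary
    n_cases: int
    category: str = ""


def phenome_scan(
    full_models: dict[tuple[str, str], ExpressionModel],
    reduced_models: dict[tuple[str, str], ExpressionModel],
    traits: list[TraitEntry],
    ld_by_gene: dict[str, np.ndarray] | None = None,
    min_cases: int = 50,
    q: float = 0.05,
) -> pd.DataFrame:
    """Scan gene-tissue models against many binary traits.

    Traits with fewer than ``min_cases`` cases are excluded. Genes are
    selected by the reduced model's imputability (iGene rule in >= 1
    tissue) — these are the genes under substantial segment control — but
    associations are computed with the full models, which have better
    power. BH FDR is applied jointly across the scan.
    """
    segment_genes = {g for (g, _), m in reduced_models.items() if igene_filter(m)}
    rows = []
    for entry in traits:
        if entry.n_cases < min_cases:
            continue
        for (gene, tissue), model in full_models.items():
            if gene not in segment_genes:
                continue
            ld = (ld_by_gene or {}).get(gene)
            try:
                a = gene_trait_association(model, entry.gwas, ld)
            except ValueError:
                continue
            rows.append(
                {"gene": gene, "tissue": tissue, "trait": entry.trait,
                 "category": entry.category, "z": a.z, "p": a.p,
                 "n_snps_used": a.n_snps_used}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    p_adj, passed = bh_fdr(out["p"].to_numpy(), q)
    out["p_fdr"] = p_adj
    out["significant"] = passed
    return out.sort_values("p").reset_index(drop=True)
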