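"""Readers and writers for the standard interchange formats.

Dosage matrices, GWAS summaries, expression, tissue similarity, and LD
matrices travel as TSV; genotypes may also come from VCF (DS format field,
falling back to GT allele counts). Trained models are stored as a TSV of
(gene, tissue, variant, weight) rows with a JSON sidecar of CV metrics.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GenotypeMatrix, GwasSummary, Variant
from .models import ExpressionModel, TissueSimilarity

logger = logging.getLogger(__name__)

_DOSAGE_META = ["snp", "chr", "pos", "ref", "alt", "maf"]


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Genotype dosages from VCF: the DS FORMAT field when present,
    otherwise alternate-allele counts from GT. Multi-allelic sites are
    dropped (with a log message); missing genotypes are mean-imputed."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants, columns = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if "DS" in (rec.FORMAT or []):
            dos = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        else:
            gts = np.asarray(rec.genotype.array())[:, :2]
            dos = np.where((gts < 0).any(axis=1), np.nan,
                           (gts > 0).sum(axis=1)).astype(float)
        alt_freq = np.nanmean(dos) / 2.0
        variants.append(
            Variant(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=rec.CHROM, pos=rec.POS,
                ref_allele=rec.REF, alt_allele=rec.ALT[0],
                maf=float(min(alt_freq, 1 - alt_freq)),
            )
        )
        columns.append(dos)
    if n_multi:
        logger.info("dropped %d multi-allelic sites from %s", n_multi, path)
    dosages = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, variants=variants,
                          dosages=dosages).impute_missing()


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Variant-major dosage TSV: metadata columns then one column per sample."""
    meta = pd.DataFrame(
        {
            "snp": [v.id for v in genotypes.variants],
            "chr": [v.chrom for v in genotypes.variants],
            "pos": [v.pos for v in genotypes.variants],
            "ref": [v.ref_allele for v in genotypes.variants],
            "alt": [v.alt_allele for v in genotypes.variants],
            "maf": [v.maf for v in genotypes.variants],
        }
    )
    dos = pd.DataFrame(genotypes.dosages.T, columns=genotypes.samples)
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DOSAGE_META if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing columns: {missing}")
    samples = [c for c in df.columns if c not in _DOSAGE_META]
    variants = [
        Variant(id=r["snp"], chrom=str(r["chr"]), pos=int(r["pos"]),
                ref_allele=r["ref"], alt_allele=r["alt"], maf=float(r["maf"]))
        for _, r in df.iterrows()
    ]
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(samples=samples, variants=variants,
                          dosages=dosages).impute_missing()


def read_gwas_tsv(path: str | Path, trait: str = "") -> GwasSummary:
    df = pd.read_csv(path, sep="\t")
    if "chr" in df.columns:
        df["chr"] = df["chr"].astype(str)
    return GwasSummary(table=df, trait=trait or Path(path).stem)


def write_gwas_tsv(gwas: GwasSummary, path: str | Path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path, tissue: str = "") -> ExpressionMatrix:
    """Expression TSV: genes as rows (first column gene id), samples as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(tissue=tissue or Path(path).stem, values=df)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_ld_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Square LD TSV with a variant-id header row and index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("LD TSV row and column variant ids differ")
    return list(df.columns), df.to_numpy(dtype=float)


def write_ld_tsv(variants: list[str], C: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(C, index=variants, columns=variants).to_csv(path, sep="\t")


def read_similarity_tsv(
    expression_path: str | Path, regulatory_path: str | Path
) -> TissueSimilarity:
    es = pd.read_csv(expression_path, sep="\t", index_col=0)
    rs = pd.read_csv(regulatory_path, sep="\t", index_col=0)
    if list(es.columns) != list(rs.columns):
        raise ValueError("similarity matrices list different tissues")
    return TissueSimilarity(
        tissues=list(es.columns),
        expression_similarity=es.to_numpy(dtype=float),
        regulatory_similarity=rs.to_numpy(dtype=float),
    )


def write_model_store(
    models: list[ExpressionModel], weights_path: str | Path, metrics_path: str | Path
) -> None:
    """TSV of (gene, tissue, scope, variant, weight) + JSON sidecar of CV
    metrics keyed gene/tissue/scope."""
    rows = []
    metrics = {}
    for m in models:
        key = f"{m.gene}|{m.tissue}|{m.scope}"
        metrics[key] = {
            "cv_r": m.cv_r, "cv_r2": m.cv_r2, "cv_p": m.cv_p,
            "n_predictors": m.n_predictors, "intercept": m.intercept,
            "lambda": m.lambda_selected,
            "variants": {
                v.id: {"chrom": v.chrom, "pos": v.pos, "ref": v.ref_allele,
                       "alt": v.alt_allele, "maf": v.maf}
                for v in m.predictor_variants
            },
        }
        for vid, w in m.weights.items():
            rows.append({"gene": m.gene, "tissue": m.tissue, "scope": m.scope,
                         "variant": vid, "weight": w})
    pd.DataFrame(rows, columns=["gene", "tissue", "scope", "variant", "weight"]).to_csv(
        weights_path, sep="\t", index=False
    )
    Path(metrics_path).write_text(json.dumps(metrics, indent=1))


def read_model_store(
    weights_path: str | Path, metrics_path: str | Path
) -> list[ExpressionModel]:
    df = pd.read_csv(weights_path, sep="\t")
    metrics = json.loads(Path(metrics_path).read_text())
    models = []
    for key, info in metrics.items():
        gene, tissue, scope = key.split("|")
        sub = df[(df["gene"] == gene) & (df["tissue"] == tissue)
                 & (df["scope"] == scope)]
        weights = dict(zip(sub["variant"], sub["weight"].astype(float)))
        variants = [
            Variant(id=vid, chrom=v["chrom"], pos=v["pos"], ref_allele=v["ref"],
                    alt_allele=v["alt"], maf=v["maf"])
            for vid, v in info["variants"].items()
        ]
        models.append(
            ExpressionModel(
                gene=gene, tissue=tissue, weights=weights, scope=scope,
                cv_r=info["cv_r"], cv_r2=info["cv_r2"], cv_p=info["cv_p"],
                n_predictors=info["n_predictors"], intercept=info["intercept"],
                lambda_selected=info["lambda"], predictor_variants=variants,
            )
        )
    return models
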