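"""Core genomic data types shared by every analysis stage.

Internal coordinates are 0-based half-open; all text I/O is 1-based
inclusive (``chr3:45,859,651-45,909,024`` style). Variant identity is keyed
on (chrom, pos, sorted allele pair) rather than rsID so that records from
different panels can be matched robustly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SEGMENT_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")

PALINDROMIC_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with its minor allele frequency.

    ``maf`` is the frequency of the minor allele, in [0, 0.5]; ``pos`` is
    1-based, matching VCF convention.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")
        if not 0.0 <= self.maf <= 0.5 + 1e-12:
            raise ValueError(f"{self.id}: maf {self.maf} outside [0, 0.5]")

    @property
    def key(self) -> tuple[str, int, tuple[str, str]]:
        """Panel-robust identity: (chrom, pos, sorted allele pair)."""
        return (self.chrom, self.pos, tuple(sorted((self.ref_allele, self.alt_allele))))

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.ref_allele, self.alt_allele}) in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class Segment:
    """A genomic interval, stored 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment: start {self.start} >= end {self.end}")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def to_text(self) -> str:
        """1-based inclusive text form; inverse of :func:`parse_segment`."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        return chrom == self.chrom and self.start < pos <= self.end

    def dilate(self, bp: int) -> "Segment":
        """Extend by ``bp`` base pairs on both sides (clipped at zero)."""
        if bp < 0:
            raise ValueError("extension must be nonnegative")
        return replace(self, start=max(self.start - bp, 0), end=self.end + bp)


def parse_segment(text: str, label: str = "") -> Segment:
    """Parse ``chr<X>:<start>-<end>`` (1-based inclusive, commas allowed)."""
    m = _SEGMENT_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed segment text: {text!r}")
    start_1b = int(m["start"].replace(",", ""))
    end_1b = int(m["end"].replace(",", ""))
    if start_1b >= end_1b:
        raise ValueError(f"empty or inverted segment: {text!r}")
    return Segment(chrom=m["chrom"], start=start_1b - 1, end=end_1b, label=label)


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with variant metadata.

    Dosages are alternate-allele counts in [0, 2]; missing entries must be
    mean-imputed (:meth:`impute_missing`) before model fitting.
    """

    samples: list[str]
    variants: list[Variant]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def impute_missing(self) -> "GenotypeMatrix":
        """Mean-impute missing dosages per variant (in place); returns self."""
        col_means = np.nanmean(self.dosages, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        nan_rows, nan_cols = np.nonzero(np.isnan(self.dosages))
        self.dosages[nan_rows, nan_cols] = col_means[nan_cols]
        return self

    def empirical_mafs(self) -> np.ndarray:
        alt_freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(alt_freq, 1.0 - alt_freq)

    def standardized(self, ddof: int = 0) -> np.ndarray:
        """Column-standardized dosages (mean 0, variance 1)."""
        x = self.dosages - self.dosages.mean(axis=0)
        sd = x.std(axis=0, ddof=ddof)
        if np.any(sd == 0):
            bad = [self.variants[i].id for i in np.nonzero(sd == 0)[0][:5]]
            raise ValueError(f"monomorphic variant(s): {bad}")
        return x / sd

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=list(self.variants),
            dosages=self.dosages[idx, :],
        )

    def variants_in_segment(self, segment: Segment) -> "GenotypeMatrix":
        mask = np.array(
            [segment.contains(v.chrom, v.pos) for v in self.variants], dtype=bool
        )
        return self.subset_variants(mask)


def maf_filter(genotypes: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep variants whose empirical minor allele frequency is >= threshold.

    The comparison is inclusive (a variant at exactly the threshold is
    retained). Idempotent; may return an empty matrix.
    """
    mafs = genotypes.empirical_mafs()
    keep = mafs >= threshold - 1e-12
    if not keep.any():
        logger.warning("maf_filter: no variant passes threshold %.3g", threshold)
    return genotypes.subset_variants(keep)


@dataclass(frozen=True)
class AlleleRecord:
    """Minimal allele-oriented effect record used for harmonization."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float


@dataclass(frozen=True)
class Harmonized:
    """Outcome of aligning a GWAS record to a model/eQTL record."""

    beta: float
    dropped: bool
    reason: str  # "ok" | "flipped" | "palindromic" | "mismatch"


def harmonize_alleles(model: AlleleRecord, gwas: AlleleRecord) -> Harmonized:
    """Align the GWAS effect to the model's effect allele.

    Matching orientation passes through; swapped effect/other alleles flip
    the GWAS beta sign; palindromic (A/T, C/G) variants are dropped because
    strand cannot be resolved; irreconcilable allele pairs are dropped.
    """
    if (model.chrom, model.pos) != (gwas.chrom, gwas.pos):
        raise ValueError(
            f"position mismatch: {model.chrom}:{model.pos} vs {gwas.chrom}:{gwas.pos}"
        )
    pair = frozenset({model.effect_allele, model.other_allele})
    if pair in PALINDROMIC_PAIRS:
        return Harmonized(beta=np.nan, dropped=True, reason="palindromic")
    if (model.effect_allele, model.other_allele) == (gwas.effect_allele, gwas.other_allele):
        return Harmonized(beta=gwas.beta, dropped=False, reason="ok")
    if (model.effect_allele, model.other_allele) == (gwas.other_allele, gwas.effect_allele):
        return Harmonized(beta=-gwas.beta, dropped=False, reason="flipped")
    return Harmonized(beta=np.nan, dropped=True, reason="mismatch")


@dataclass
class GwasSummary:
    """Per-variant marginal summary statistics for one trait.

    Backed by a DataFrame with columns ``snp, chr, pos, ea, oa, beta, se, n``
    and optionally ``z``. ``z`` is reconstructed as beta/se when absent.
    """

    table: pd.DataFrame
    trait: str = ""

    REQUIRED = ("snp", "chr", "pos", "ea", "oa", "beta", "se", "n")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"GWAS summary missing columns: {missing}")
        t = self.table.copy()
        if "z" not in t.columns:
            t["z"] = t["beta"] / t["se"]
        else:
            both = t["z"].notna() & t["beta"].notna() & t["se"].notna()
            resid = np.abs(t.loc[both, "z"] - t.loc[both, "beta"] / t.loc[both, "se"])
            if (resid > 1e-6).any():
                raise ValueError("inconsistent z vs beta/se in GWAS summary")
        if (t["se"] <= 0).any():
            raise ValueError("non-positive se in GWAS summary")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def standardized_beta(self) -> np.ndarray:
        """Per-SD marginal effects z/sqrt(n), the scale the local-heritability
        estimator assumes."""
        return (self.table["z"] / np.sqrt(self.table["n"])).to_numpy()

    def lookup(self) -> dict[tuple[str, int, tuple[str, str]], int]:
        """Row index keyed on (chrom, pos, sorted allele pair)."""
        out: dict[tuple[str, int, tuple[str, str]], int] = {}
        for i, row in self.table.iterrows():
            out[(str(row["chr"]), int(row["pos"]), tuple(sorted((row["ea"], row["oa"]))))] = i
        return out


@dataclass
class ExpressionMatrix:
    """Residualized expression for one tissue: genes x samples."""

    tissue: str
    values: pd.DataFrame  # index: genes, columns: samples

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError(f"non-finite expression values in tissue {self.tissue}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def gene_vector(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)
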