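"""LD matrices, Ledoit-Wolf projection, LD scores, and pseudoinverse utilities.

The projected LD matrix pi(C) is the Ledoit-Wolf linear shrinkage of the
observed correlation matrix C_hat toward a scaled identity, chosen to
minimize the expected squared Frobenius distance to the unobserved true LD
matrix C:

    pi(C) = (b^2 m / d^2) I + (a^2 / d^2) C_hat

with m = <C_hat, I>, d^2 = ||C_hat - m I||^2,
b^2 = min(d^2, (1/n^2) sum_k ||X_k X_k^T - C_hat||^2), a^2 = d^2 - b^2.

All Frobenius inner products and norms here are normalized by p
(<A, B> = tr(A B^T)/p), the original Ledoit-Wolf convention, so that m is
the mean diagonal entry (1 for a correlation matrix) and the four scalars
share a scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix

DEFAULT_PINV_TOL = 1e-8


@dataclass
class LDMatrix:
    """Variant correlation matrix with its effective rank."""

    variants: list[str]
    C_hat: np.ndarray
    n_panel: int
    rank: int
    tol: float = DEFAULT_PINV_TOL

    @property
    def p(self) -> int:
        return self.C_hat.shape[0]


@dataclass
class ProjectedLD:
    """Ledoit-Wolf components and the projected matrix for one panel."""

    base: LDMatrix
    m: float
    d2: float
    b2: float
    a2: float
    pi_C: np.ndarray

    @property
    def shrinkage(self) -> float:
        """Weight on the identity target, b^2/d^2 in [0, 1]."""
        return self.b2 / self.d2 if self.d2 > 0 else 0.0


def _frob_inner(a: np.ndarray, b: np.ndarray) -> float:
    """p-normalized Frobenius inner product tr(a b^T)/p."""
    return float(np.sum(a * b) / a.shape[0])


def empirical_ld(genotypes: GenotypeMatrix, tol: float = DEFAULT_PINV_TOL) -> LDMatrix:
    """Pearson correlation of dosage columns, with SVD effective rank.

    Raises on monomorphic variants (correlation undefined), naming them.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need >= 2 samples to estimate LD")
    x = genotypes.standardized(ddof=0)  # raises naming monomorphic variants
    n = genotypes.n_samples
    C = (x.T @ x) / n
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    rank = matrix_rank_svd(C, tol)
    return LDMatrix(
        variants=[v.id for v in genotypes.variants],
        C_hat=C,
        n_panel=n,
        rank=rank,
        tol=tol,
    )


def matrix_rank_svd(C: np.ndarray, tol: float = DEFAULT_PINV_TOL) -> int:
    s = np.linalg.svd(C, compute_uv=False)
    if s.size == 0:
        return 0
    return int(np.sum(s > tol * s[0]))


def ledoit_wolf_project(
    genotypes: GenotypeMatrix, tol: float = DEFAULT_PINV_TOL
) -> ProjectedLD:
    """Compute the projected LD matrix pi(C) from panel genotypes.

    Genotypes are standardized per variant so that C_hat = X^T X / n is the
    correlation matrix and the per-subject outer products X_k X_k^T live on
    the same (correlation) scale. When d^2 is numerically zero (C_hat already
    a scaled identity) the observed matrix is returned unshrunk.
    """
    base = empirical_ld(genotypes, tol=tol)
    x = genotypes.standardized(ddof=0)
    n, p = x.shape
    C = base.C_hat
    m = _frob_inner(C, np.eye(p))
    dev = C - m * np.eye(p)
    d2 = _frob_inner(dev, dev)
    if d2 <= tol:
        return ProjectedLD(base=base, m=m, d2=d2, b2=0.0, a2=0.0, pi_C=C.copy())
    # (1/n^2) sum_k ||X_k X_k^T - C_hat||^2, normalized by p like d2.
    # Expanded: (1/n^2) sum_k [ <XkXk^T, XkXk^T> - 2<XkXk^T, C> + <C, C> ]
    # where <Xk Xk^T, Xk Xk^T> = (Xk.Xk)^2 / p and
    # sum_k <Xk Xk^T, C> = tr(X C X^T)/p = n <C, C> (since C = X^T X / n).
    sq_norms = np.einsum("ij,ij->i", x, x)  # Xk . Xk per subject
    cc = _frob_inner(C, C)
    b2_raw = (np.sum(sq_norms**2) / p - n * cc) / n**2
    b2 = float(min(d2, max(b2_raw, 0.0)))
    a2 = d2 - b2
    pi_C = (b2 * m / d2) * np.eye(p) + (a2 / d2) * C
    return ProjectedLD(base=base, m=m, d2=d2, b2=b2, a2=a2, pi_C=pi_C)


def ld_scores(ld: np.ndarray) -> np.ndarray:
    """Per-variant LD score: the row sum of the LD matrix."""
    ld = np.asarray(ld, dtype=float)
    if ld.ndim != 2 or ld.shape[0] != ld.shape[1]:
        raise ValueError("LD matrix must be square")
    return ld.sum(axis=1)


def inverse_or_pseudoinverse(
    C: np.ndarray, tol: float = DEFAULT_PINV_TOL
) -> tuple[np.ndarray, int]:
    """Exact inverse when full rank, else Moore-Penrose pseudoinverse.

    Returns (inverse, effective rank q). Singular values below
    tol * s_max are treated as zero. Asymmetric input is rejected.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    # symmetric eigendecomposition doubles as the SVD here
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    s_max = np.max(np.abs(w)) if w.size else 0.0
    keep = np.abs(w) > tol * s_max
    q = int(keep.sum())
    inv_w = np.zeros_like(w)
    inv_w[keep] = 1.0 / w[keep]
    return (V * inv_w) @ V.T, q
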