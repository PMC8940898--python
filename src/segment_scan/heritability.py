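"""Summary-statistics local heritability with LD-sensitivity diagnostics.

The region-level estimator takes standardized marginal effects
beta_hat (z/sqrt(n) units), the regional LD matrix C, the GWAS sample
size n, and returns

    r2_L = ((beta' C^{-1} beta - q/n) / (n - q)) * n

where q = rank(C) replaces the variant count p when C is rank-deficient
(the pseudoinverse route); its sampling variance is

    var(r2_L) = (1 - q^2/n^2)^{-1} * (1 - r2_L)/n * (4 r2_L + 2 q (1 - r2_L)/n).

Two-SNP closed forms and an LD perturbation report are provided as
diagnostics for how the estimate moves with errors in the LD matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ld import DEFAULT_PINV_TOL, inverse_or_pseudoinverse


@dataclass
class HeritabilityEstimate:
    """Local heritability point estimate and sampling variance."""

    r2_local: float
    variance: float
    n: int
    p: int
    q_rank: int
    ld_mode: str = "observed"  # "observed" | "projected" | "true"

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def variance_local_h2(r2_local: float, n: int, p_or_q: int) -> float:
    """Sampling variance of the local heritability estimate."""
    if n <= p_or_q:
        raise ValueError(f"need n > p (or q); got n={n}, p={p_or_q}")
    ratio = p_or_q / n
    return float(
        (1.0 / (1.0 - ratio**2))
        * ((1.0 - r2_local) / n)
        * (4.0 * r2_local + 2.0 * p_or_q * (1.0 - r2_local) / n)
    )


def h2_quadratic_form(beta_std: np.ndarray, M: np.ndarray, n: int, q: int) -> float:
    """The estimator as an explicit function of the (inverted) LD argument.

    ``M`` plays the role of C^{-1} (or the pseudoinverse). Exposed separately
    because the LD-sensitivity report differentiates the estimator with the
    quadratic form taken directly in the matrix argument.
    """
    beta_std = np.asarray(beta_std, dtype=float)
    return float((beta_std @ M @ beta_std - q / n) / (n - q) * n)


def estimate_local_h2(
    beta_std: np.ndarray,
    ld: np.ndarray,
    n: int,
    ld_mode: str = "observed",
    *,
    rank_adjusted: bool = True,
    tol: float = DEFAULT_PINV_TOL,
) -> HeritabilityEstimate:
    """Estimate local heritability from standardized marginal effects.

    ``beta_std`` must be on the per-SD scale (z/sqrt(n)). With
    ``rank_adjusted`` (default) the effective rank q of the LD matrix
    replaces the variant count p in both the point estimate and its
    variance; disable it to reproduce the full-rank textbook form exactly
    (p is then used even if C is singular).

    Negative estimates are legitimate sampling outcomes and are returned
    as-is; flooring at zero would bias averages over replicates.
    """
    beta_std = np.asarray(beta_std, dtype=float)
    ld = np.asarray(ld, dtype=float)
    p = ld.shape[0]
    if beta_std.shape != (p,):
        raise ValueError(f"beta length {beta_std.shape} vs LD dimension {p}")
    C_inv, q = inverse_or_pseudoinverse(ld, tol=tol)
    dof = q if rank_adjusted else p
    if n <= dof:
        raise ValueError(f"need n > rank(C); got n={n}, q={dof}")
    r2 = h2_quadratic_form(beta_std, C_inv, n, dof)
    var = variance_local_h2(r2, n, dof)
    return HeritabilityEstimate(
        r2_local=r2, variance=var, n=n, p=p, q_rank=q, ld_mode=ld_mode
    )


def two_snp_closed_forms(
    beta1: float, beta2: float, rho: float, n: int
) -> tuple[float, float]:
    """Closed-form two-SNP estimate and its derivative in the LD entry rho.

    For |rho| < 1:
        estimate  = [n (b1^2 + b2^2 - 2 rho b1 b2) - 2] / (n - 2)
        d/d rho   = -2 b1 b2 n / (n - 2)
    At rho = 1 the LD matrix is singular; the pseudoinverse route gives
        estimate  = [n (b1^2/4 + b2^2/4 + b1 b2/2) - 1] / (n - 1)
    and the derivative is reported as nan (the estimate is not
    differentiable across the rank drop).
    """
    if abs(rho) < 1.0:
        est = (n * (beta1**2 + beta2**2 - 2.0 * rho * beta1 * beta2) - 2.0) / (n - 2)
        deriv = -2.0 * beta1 * beta2 * n / (n - 2)
        return float(est), float(deriv)
    if rho == 1.0:
        est = (n * (0.25 * beta1**2 + 0.25 * beta2**2 + 0.5 * beta1 * beta2) - 1.0) / (
            n - 1
        )
        return float(est), float("nan")
    raise ValueError(f"rho must be in [-1, 1); got {rho}")


@dataclass
class SensitivityReport:
    """Entrywise derivative of the local heritability estimate in C_ij."""

    derivative: np.ndarray  # p x p, entry (i,j) = b_i b_j n/(n - q)
    n: int
    q_rank: int


def ld_sensitivity(
    beta_std: np.ndarray,
    ld: np.ndarray,
    n: int,
    *,
    tol: float = DEFAULT_PINV_TOL,
) -> SensitivityReport:
    """How the heritability estimate responds to a perturbation of LD.

    Entry (i, j) is beta_i beta_j * n/(n - rank(C)): the derivative of the
    estimator's quadratic form with respect to the single matrix entry
    (i, j), under the convention that perturbing C_ij propagates one-to-one
    into the matrix argument (trace contribution 1 per entry). A symmetric
    perturbation of the pair (i, j), (j, i) therefore moves the estimate by
    twice the off-diagonal entry.
    """
    beta_std = np.asarray(beta_std, dtype=float)
    ld = np.asarray(ld, dtype=float)
    if beta_std.shape[0] != ld.shape[0]:
        raise ValueError("beta length does not match LD dimension")
    _, q = inverse_or_pseudoinverse(ld, tol=tol)
    if n <= q:
        raise ValueError(f"need n > rank(C); got n={n}, q={q}")
    deriv = np.outer(beta_std, beta_std) * (n / (n - q))
    return SensitivityReport(derivative=deriv, n=n, q_rank=q)
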