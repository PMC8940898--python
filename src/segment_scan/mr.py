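"""Mendelian randomization: instrument filtering, IVW, and the penalized
joint estimator.

The penalized estimator regresses per-instrument GWAS effects theta_j on
eQTL effects beta_j while jointly fitting a per-instrument heterogeneity
term v_j (absorbing horizontal pleiotropy and confounding) and an LD-score
term w l_j, all under an L1 penalty:

    argmin_{u, v, w}  sum_j (theta_j - u beta_j - v_j - w l_j)^2
                      + lambda (||v||_1 + |u| + |w|)

The causal-effect estimate is u at a cross-validation-selected lambda.
Because the L1 penalty shrinks u toward zero, a "relaxed" refit — ordinary
least squares on the selected support — is available and recommended when
an unbiased point estimate matters more than selection stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso

from .core import PALINDROMIC_PAIRS


@dataclass
class Instrument:
    """One IV: its eQTL and (harmonized) GWAS marginal effects."""

    variant: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    p_exposure: float
    beta_outcome: float
    se_outcome: float
    ld_score: float = 1.0


@dataclass
class IVSet:
    """Surviving instruments plus the retained IV-IV correlation."""

    instruments: list[Instrument]
    ld: np.ndarray  # correlation among surviving instruments
    n_palindromic_removed: int = 0
    n_clumped_out: int = 0

    def __len__(self) -> int:
        return len(self.instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        b = np.array([iv.beta_exposure for iv in self.instruments])
        t = np.array([iv.beta_outcome for iv in self.instruments])
        se = np.array([iv.se_outcome for iv in self.instruments])
        l = np.array([iv.ld_score for iv in self.instruments])
        return b, t, se, l


def build_iv_set(
    instruments: list[Instrument],
    ld: np.ndarray,
    clump_p: float = 0.05,
    clump_r2: float = 0.1,
) -> IVSet:
    """Filter instruments: drop palindromic variants, then greedily clump.

    Clumping sorts by eQTL p-value ascending (ties broken by genomic
    position) and keeps a variant iff its p-value is below ``clump_p`` and
    its r^2 with every already-kept variant is below ``clump_r2``. Residual
    correlation among survivors is retained and passed downstream.
    """
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (len(instruments), len(instruments)):
        raise ValueError("LD matrix does not match instrument count")
    keep_idx = [
        i for i, iv in enumerate(instruments)
        if frozenset({iv.effect_allele, iv.other_allele}) not in PALINDROMIC_PAIRS
    ]
    n_palin = len(instruments) - len(keep_idx)
    order = sorted(keep_idx, key=lambda i: (instruments[i].p_exposure,
                                            instruments[i].pos))
    kept: list[int] = []
    for i in order:
        if instruments[i].p_exposure >= clump_p:
            continue
        if all(ld[i, j] ** 2 < clump_r2 for j in kept):
            kept.append(i)
    if not kept:
        raise ValueError("no instruments survive palindrome removal and clumping")
    kept.sort()
    return IVSet(
        instruments=[instruments[i] for i in kept],
        ld=ld[np.ix_(kept, kept)],
        n_palindromic_removed=n_palin,
        n_clumped_out=len(keep_idx) - len(kept),
    )


def ivw(iv: IVSet | tuple[np.ndarray, ...]) -> tuple[float, float]:
    """Fixed-effect inverse-variance-weighted estimate and its SE.

    alpha = sum_j theta_j beta_j / se_j^2 / sum_j beta_j^2 / se_j^2.
    """
    if isinstance(iv, IVSet):
        b, t, se, _ = iv.arrays()
    else:
        b, t, se = iv[0], iv[1], iv[2]
    denom = np.sum(b**2 / se**2)
    if denom == 0:
        raise ValueError("all exposure effects are zero")
    alpha = float(np.sum(t * b / se**2) / denom)
    return alpha, float(np.sqrt(1.0 / denom))


@dataclass
class MRFit:
    """Penalized MR fit: causal effect, heterogeneity, LD-score effect."""

    alpha_hat: float
    v_hat: np.ndarray
    w_hat: float
    lambda_: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    seed: int = 0
    alpha_penalized: float = float("nan")


def _design(beta: np.ndarray, l: np.ndarray) -> np.ndarray:
    J = len(beta)
    return np.column_stack([beta, np.eye(J), l])


def _solve_penalized(
    beta: np.ndarray, theta: np.ndarray, l: np.ndarray, lam: float, max_iter: int = 50_000
) -> np.ndarray:
    """Coefficients (u, v_1..J, w) of the L1 problem at one lambda.

    sklearn's lasso objective is 1/(2J) ||y - A x||^2 + a ||x||_1, so the
    printed-objective lambda maps to a = lambda / (2J).
    """
    J = len(beta)
    A = _design(beta, l)
    # standardize columns (glmnet-style) so the penalty acts on a common
    # scale; raw exposure effects are often << 1 and an unscaled |u| penalty
    # would then never activate the causal term
    scale = A.std(axis=0)
    scale[scale == 0] = 1.0
    est = Lasso(alpha=lam / (2.0 * J), fit_intercept=False, max_iter=max_iter,
                tol=1e-8)
    est.fit(A / scale, theta)
    return est.coef_ / scale


def _relaxed_refit(
    beta: np.ndarray, theta: np.ndarray, l: np.ndarray, coef: np.ndarray
) -> np.ndarray:
    """OLS on the L1-selected support (coefficients off-support stay 0)."""
    A = _design(beta, l)
    support = np.nonzero(coef)[0]
    out = np.zeros_like(coef)
    if support.size == 0:
        return out
    sol, *_ = np.linalg.lstsq(A[:, support], theta, rcond=None)
    out[support] = sol
    return out


def _robust_refine(
    beta: np.ndarray, theta: np.ndarray, l: np.ndarray, coef: np.ndarray
) -> np.ndarray:
    """One re-selection pass on the relaxed fit.

    The penalized fit under-flags invalid instruments because its shrunken
    causal term distorts the residuals the selection sees; re-flagging
    against the relaxed fit's residuals (beyond 3 robust SDs) and refitting
    (u, w) on the remaining instruments removes the resulting leak-through
    bias. Flagged instruments keep their residual as the heterogeneity term.
    """
    J = len(beta)
    u, w = coef[0], coef[-1]
    keep = np.ones(J, bool)
    for _ in range(10):  # iterate flag/refit to a fixed point (IRLS-style)
        r = theta - u * beta - w * l
        med = np.median(r[keep])
        sigma = 1.4826 * np.median(np.abs(r[keep] - med))
        new_keep = np.abs(r - med) <= 3.0 * sigma if sigma > 0 else np.ones(J, bool)
        if new_keep.sum() < 3:
            break
        A = np.column_stack([beta[new_keep], l[new_keep]])
        sol, *_ = np.linalg.lstsq(A, theta[new_keep], rcond=None)
        u, w = float(sol[0]), float(sol[1])
        if np.array_equal(new_keep, keep):
            keep = new_keep
            break
        keep = new_keep
    out = np.zeros_like(coef)
    out[0], out[-1] = u, w
    resid = theta - u * beta - w * l
    out[1:-1] = np.where(keep, 0.0, resid)
    return out


def _fit_at_lambda(
    beta: np.ndarray, theta: np.ndarray, l: np.ndarray, lam: float, relaxed: bool
) -> np.ndarray:
    coef = _solve_penalized(beta, theta, l, lam)
    if relaxed:
        coef = _robust_refine(beta, theta, l, _relaxed_refit(beta, theta, l, coef))
    return coef


def mr_jti(
    iv: IVSet,
    lambda_grid: np.ndarray | None = None,
    n_boot: int = 500,
    seed: int = 0,
    *,
    n_folds: int = 5,
    relaxed: bool = True,
    ci_level: float = 0.95,
) -> MRFit:
    """Penalized MR with CV-selected lambda and a percentile bootstrap CI.

    Lambda is chosen by K-fold cross-validation over instruments (held-out
    instruments are predicted from u beta_j + w l_j; their heterogeneity
    terms are unidentified out of fold and predicted as zero). The CI
    resamples instruments with replacement ``n_boot`` times and refits at
    the selected lambda.
    """
    if len(iv) < 3:
        raise ValueError("need at least 3 instruments")
    b, t, _, l = iv.arrays()
    if np.all(b == 0):
        raise ValueError("degenerate IV set: all exposure effects zero")
    J = len(b)
    if lambda_grid is None:
        lam_max = 2.0 * max(np.max(np.abs(t)), 1e-12)  # v_j alone can fit each theta
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-4, 30)

    rng = np.random.default_rng(seed)
    folds = np.resize(np.arange(n_folds), J)
    rng.shuffle(folds)
    fold_err = np.full((len(lambda_grid), n_folds), np.nan)
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        if tr.sum() < 2 or te.sum() == 0:
            continue
        for li, lam in enumerate(lambda_grid):
            # held-out instruments have no heterogeneity term of their own;
            # they are predicted from the causal and LD-score components
            coef = _fit_at_lambda(b[tr], t[tr], l[tr], lam, relaxed)
            u, w = coef[0], coef[-1]
            pred = u * b[te] + w * l[te]
            fold_err[li, f] = np.mean((t[te] - pred) ** 2)
    cvm = np.nanmean(fold_err, axis=1)
    n_eff = np.sum(~np.isnan(fold_err), axis=1)
    cvs = np.nanstd(fold_err, axis=1, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    best = int(np.nanargmin(cvm))
    # one-SE rule toward the sparse end: prediction error is flat near its
    # minimum, and the relaxed refit needs the heterogeneity support sparse
    if np.isfinite(cvs[best]):
        best = int(np.nonzero(cvm <= cvm[best] + cvs[best])[0][0])
    lam = float(lambda_grid[best])

    coef_pen = _solve_penalized(b, t, l, lam)
    coef = _fit_at_lambda(b, t, l, lam, relaxed) if relaxed else coef_pen
    alpha_hat = float(coef[0])

    boot = np.empty(n_boot)
    for r in range(n_boot):
        idx = rng.integers(0, J, size=J)
        bb, tb, lb = b[idx], t[idx], l[idx]
        if np.all(bb == 0):
            boot[r] = 0.0
            continue
        boot[r] = _fit_at_lambda(bb, tb, lb, lam, relaxed)[0]
    lo_q = (1.0 - ci_level) / 2.0
    ci_low = float(np.quantile(boot, lo_q)) if n_boot else float("nan")
    ci_high = float(np.quantile(boot, 1.0 - lo_q)) if n_boot else float("nan")
    # percentile intervals are widened, if needed, to contain the point estimate
    if n_boot:
        ci_low = min(ci_low, alpha_hat)
        ci_high = max(ci_high, alpha_hat)
    return MRFit(
        alpha_hat=alpha_hat,
        v_hat=coef[1:-1].copy(),
        w_hat=float(coef[-1]),
        lambda_=lam,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        seed=seed,
        alpha_penalized=float(coef_pen[0]),
    )
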