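"""Semi-parallel SNP association statistics.

After the covariate-only logistic fit, every SNP is scored jointly through a
single round of weighted linear algebra instead of ``m`` separate refits.
With ``p`` the fitted probabilities, ``W = diag(p_i (1 - p_i))``, and the
working response ``z_i = x_i^T beta + (y_i - p_i) / w_i``, the per-SNP score
is the one-step Wald statistic

    t_j = z*^T W S*_j / sqrt(s*2_j)

where ``z*`` and ``S*_j`` are the residuals of ``z`` and the SNP column after
projecting out the covariate span under the ``sqrt(W)`` metric.  At the point
of convergence the covariate gradient ``X^T (y - p)`` vanishes, and the
statistic collapses to the simplified form

    numerator_j = (y - p)^T S_j
    s*2_j       = colsums(W * (S .* S))_j - A_j^T G^{-1} A_j

with the Gram matrix ``G = X^T W X`` and cross-product ``A = X^T W S``; for
binary genotypes ``S .* S = S``.  Both paths are implemented: the simplified
pipeline (:func:`stat_numerator`, :func:`stat_denominator`) and the explicit
projection oracle (:func:`oracle_semiparallel`) they must agree with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg as sla
from scipy.stats import norm

from .core_model import (
    Dataset,
    FitConfig,
    ModelState,
    SigmoidLUT,
    compute_weights,
    fit_logistic_gd,
    predict_probabilities,
)


class SingularMatrixError(np.linalg.LinAlgError):
    """Raised when a Gram matrix is not invertible (or not positive definite)."""


@dataclass
class GramData:
    """Precomputed Gram blocks: ``G = X^T W X``, ``A = X^T W S``, ``eps = 4G - I``."""

    G: np.ndarray
    A: Optional[np.ndarray] = None

    @property
    def eps(self) -> np.ndarray:
        return 4.0 * self.G - np.eye(self.G.shape[0])


@dataclass
class StatResult:
    snp_ids: list[str]
    numerator: np.ndarray
    denominator: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    sign: np.ndarray
    masked: np.ndarray
    log_stat: Optional[np.ndarray] = None


@dataclass
class OracleState:
    """Explicit projection intermediates (kept for inspection in tests)."""

    z: np.ndarray
    zprime: np.ndarray
    Sprime: np.ndarray
    projector: np.ndarray
    zstar_prime: np.ndarray
    Sstar_prime: np.ndarray


def compute_gram(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """``G = X^T diag(w) X``; symmetrised to kill rounding asymmetry."""
    X = np.asarray(X, float)
    w = np.asarray(w, float)
    if w.shape[0] != X.shape[0]:
        raise ValueError("length of w must equal the number of rows of X")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    G = X.T @ (w[:, None] * X)
    return 0.5 * (G + G.T)


def compute_A(X: np.ndarray, w: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Cross-product ``A = X^T diag(w) S`` of shape (k+1) x m."""
    X, w, S = np.asarray(X, float), np.asarray(w, float), np.asarray(S, float)
    if not (X.shape[0] == w.shape[0] == S.shape[0]):
        raise ValueError("X, w and S must share their row dimension")
    return X.T @ (w[:, None] * S)


def invert_G_taylor(G: np.ndarray, order: int) -> np.ndarray:
    """Neumann-series inverse ``4 * sum_{t<=order} (-(4G - I))^t``.

    The expansion is around ``G = I/4`` (the Gram matrix of orthonormal
    columns under the maximal logistic weight 1/4) and converges iff the
    spectral radius of ``eps = 4G - I`` is below 1.  ``order=0`` returns
    ``4I``, which on well-balanced data is already a usable approximation.
    """
    G = np.asarray(G, float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G must be square")
    if order < 0:
        raise ValueError("order must be nonnegative")
    eye = np.eye(G.shape[0])
    eps = 4.0 * G - eye
    rho = float(np.max(np.abs(np.linalg.eigvalsh(0.5 * (eps + eps.T)))))
    if rho >= 1.0:
        warnings.warn(
            f"Neumann series diverges: spectral radius of 4G - I is {rho:.3g} >= 1",
            RuntimeWarning,
            stacklevel=2,
        )
    acc = eye.copy()
    term = eye
    for _ in range(order):
        term = term @ (-eps)
        acc = acc + term
    return 4.0 * acc


def invert_G_exact(G: np.ndarray) -> np.ndarray:
    """Exact inverse through the Cholesky factorization of G."""
    G = np.asarray(G, float)
    try:
        c, low = sla.cho_factor(G, lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(f"G is not positive definite: {exc}") from exc
    return sla.cho_solve((c, low), np.eye(G.shape[0]))


def stat_numerator(y: np.ndarray, p: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Score numerator ``(y - p)^T S`` — one residual dot product per SNP."""
    y, p, S = np.asarray(y, float), np.asarray(p, float), np.asarray(S, float)
    if not (y.shape[0] == p.shape[0] == S.shape[0]):
        raise ValueError("y, p and S must share their row dimension")
    return S.T @ (y - p)


def stat_denominator(
    w: np.ndarray,
    S: np.ndarray,
    A: np.ndarray,
    Ginv: np.ndarray,
    binary_S: bool = True,
    check_negative: bool = True,
) -> np.ndarray:
    """Squared projection norm ``s*2_j = sum_i w_i S_ij^2 - A_j^T Ginv A_j``.

    For binary S the elementwise square is S itself.  A negative result beyond
    rounding noise with an exact ``Ginv`` signals inconsistent inputs and
    raises; with an approximate (Taylor) inverse pass ``check_negative=False``.
    """
    w, S, A = np.asarray(w, float), np.asarray(S, float), np.asarray(A, float)
    if w.shape[0] != S.shape[0] or A.shape[1] != S.shape[1]:
        raise ValueError("inconsistent dimensions among w, S, A")
    Ssq = S if binary_S else S * S
    lead = Ssq.T @ w
    quad = np.einsum("ij,ij->j", A, np.asarray(Ginv, float) @ A)
    den = lead - quad
    tol = 1e-9 * max(1.0, float(lead.max(initial=0.0)))
    if check_negative and den.min(initial=0.0) < -tol:
        raise ValueError(
            f"negative denominator {den.min():.3g} with exact Gram inverse; "
            "inputs are inconsistent"
        )
    if check_negative:
        np.clip(den, 0.0, None, out=den)
    return den


def compute_tstat(
    numerator: np.ndarray, denominator: np.ndarray, eps_den: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """``t_j = numerator_j / sqrt(denominator_j)`` with degenerate SNPs masked.

    Entries whose denominator is at or below ``eps_den`` (monomorphic or
    covariate-collinear SNPs) come back NaN with ``mask=True`` rather than
    being silently dropped or zeroed.
    """
    num = np.asarray(numerator, float)
    den = np.asarray(denominator, float)
    if num.shape != den.shape:
        raise ValueError("numerator and denominator must have equal length")
    if den.min(initial=0.0) < -eps_den:
        raise ValueError(f"negative denominator {den.min():.3g}")
    mask = den <= eps_den
    t = np.full_like(num, np.nan)
    np.divide(num, np.sqrt(np.where(mask, 1.0, den)), out=t, where=~mask)
    t[mask] = np.nan
    return t, mask


def tstat_to_pvalue(t: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value ``2 * (1 - Phi(|t|))``; NaN entries propagate."""
    t = np.asarray(t, float)
    return 2.0 * norm.sf(np.abs(t))


def oracle_semiparallel(
    data: Dataset, beta: np.ndarray
) -> tuple[StatResult, OracleState]:
    """Reference statistic from explicit weighted orthogonal projections.

    Builds the working response, applies the ``sqrt(W)`` change of variable
    and projects onto the orthogonal complement of the covariate span — the
    unsimplified form of the score.  Quadratic in ``n``: use on moderate
    sample sizes (it exists to validate the fast path, not to replace it).
    """
    data.validate()
    X = np.asarray(data.X, float)
    y = np.asarray(data.y, float)
    S = np.asarray(data.S, float)
    p = predict_probabilities(X, beta)
    w = compute_weights(p)
    if np.any(w <= 0):
        raise ValueError("oracle requires p strictly inside (0,1) so that w > 0")
    z = X @ beta + (y - p) / w
    sw = np.sqrt(w)
    Xp = sw[:, None] * X
    zp = sw * z
    Sp = sw[:, None] * S
    Q, R = np.linalg.qr(Xp)
    diag = np.abs(np.diag(R))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        raise SingularMatrixError("sqrt(W) X is rank deficient")
    P = Q @ Q.T
    zstar = zp - Q @ (Q.T @ zp)
    Sstar = Sp - Q @ (Q.T @ Sp)
    num = Sstar.T @ zstar
    den = np.einsum("ij,ij->j", Sstar, Sstar)
    t, mask = compute_tstat(num, den, eps_den=1e-12 * data.n)
    res = StatResult(
        snp_ids=list(data.snp_ids),
        numerator=num,
        denominator=den,
        tstat=t,
        pvalue=tstat_to_pvalue(t),
        sign=np.sign(num),
        masked=mask,
    )
    state = OracleState(
        z=z, zprime=zp, Sprime=Sp, projector=P, zstar_prime=zstar, Sstar_prime=Sstar
    )
    return res, state


def semiparallel_scan(
    data: Dataset,
    cfg: Optional[FitConfig] = None,
    lut: Optional[SigmoidLUT] = None,
    ginv_mode: str = "exact",
    taylor_order: int = 2,
    state: Optional[ModelState] = None,
) -> tuple[StatResult, ModelState]:
    """Full simplified pipeline: fit, weight, precompute G and A, score all SNPs.

    ``ginv_mode`` selects the Gram inversion: ``"exact"`` (Cholesky) or
    ``"taylor"`` (Neumann series of the given order).  A precomputed
    ``ModelState`` may be supplied to skip the fit.
    """
    data.validate()
    cfg = cfg or FitConfig()
    if state is None:
        state = fit_logistic_gd(data, cfg, lut=lut)
    p = predict_probabilities(data.X, state.beta, cfg.sigmoid_mode, lut)
    w = compute_weights(p)
    G = compute_gram(data.X, w)
    A = compute_A(data.X, w, data.S)
    if ginv_mode == "exact":
        Ginv = invert_G_exact(G)
    elif ginv_mode == "taylor":
        Ginv = invert_G_taylor(G, taylor_order)
    else:
        raise ValueError(f"unknown ginv_mode {ginv_mode!r}")
    num = stat_numerator(data.y, p, data.S)
    den = stat_denominator(
        w, data.S, A, Ginv,
        binary_S=not data.dosage,
        check_negative=(ginv_mode == "exact"),
    )
    if ginv_mode != "exact":
        # approximate inverses can undershoot; degenerate entries get masked
        np.clip(den, 0.0, None, out=den)
    t, mask = compute_tstat(num, den, eps_den=1e-12 * data.n)
    res = StatResult(
        snp_ids=list(data.snp_ids),
        numerator=num,
        denominator=den,
        tstat=t,
        pvalue=tstat_to_pvalue(t),
        sign=np.sign(num),
        masked=mask,
    )
    return res, state
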