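"""Covariate-only logistic regression by fixed-step gradient descent.

This is the first stage of the semi-parallel GWAS scan: fit a logistic model
``P(y=1|x) = sigma(x^T beta)`` using the covariates alone.  Two evaluation
modes for the sigmoid are supported:

* ``exact`` -- the usual ``1/(1+exp(-x))``;
* ``lut``   -- a clamped nearest-entry lookup into a table of sigmoid samples
  on a fixed interval.  This reproduces, in plain arithmetic, the behaviour of
  table-based function evaluation as used by encrypted or fixed-function
  backends, where the nonlinearity can only be applied through a discretized
  table of ``d+1`` levels over a bounded input range.

The gradient-descent update is written in the "bookkeeping" form used by such
backends: a constant vector ``e_j = alpha * sum_i X_ij * y_i`` is added and a
per-iteration vector ``Delta_j = alpha * sum_i sigma(u_i) * X_ij`` subtracted,
which is algebraically identical to ``beta <- beta + alpha * X^T (y - sigma(X beta))``.
The table stores bare sigmoid values; the step size and the covariate values
are applied in the update itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.special import expit


class DataValidationError(ValueError):
    """Raised when an input dataset violates its structural invariants."""


class DivergenceError(FloatingPointError):
    """Raised when gradient descent produces non-finite coefficients."""


@dataclass
class Dataset:
    """GWAS inputs: covariates ``X`` (with intercept), outcome ``y``, genotypes ``S``.

    ``X`` is ``n x (k+1)`` with the first column all ones, ``y`` is a binary
    vector of length ``n`` and ``S`` is an ``n x m`` genotype matrix, binary
    unless ``dosage`` is set (then entries in {0,1,2} are allowed).
    """

    X: np.ndarray
    y: np.ndarray
    S: np.ndarray
    snp_ids: Sequence[str]
    dosage: bool = False

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.S.shape[1]

    @property
    def k(self) -> int:
        """Number of covariates excluding the intercept column."""
        return self.X.shape[1] - 1

    def validate(self) -> "Dataset":
        X, y, S = np.asarray(self.X, float), np.asarray(self.y), np.asarray(self.S)
        if X.ndim != 2 or y.ndim != 1 or S.ndim != 2:
            raise DataValidationError("X and S must be matrices, y a vector")
        n = X.shape[0]
        if y.shape[0] != n or S.shape[0] != n:
            raise DataValidationError(
                f"row mismatch: X has {n} rows, y {y.shape[0]}, S {S.shape[0]}"
            )
        if not np.all(np.isfinite(X)):
            raise DataValidationError("X contains non-finite values")
        if not np.isin(y, (0, 1)).all():
            raise DataValidationError("y must be binary 0/1")
        allowed = (0, 1, 2) if self.dosage else (0, 1)
        if not np.isin(S, allowed).all():
            raise DataValidationError(
                f"S entries must be in {allowed}"
                + ("" if self.dosage else " (pass dosage=True for 0/1/2 genotypes)")
            )
        if n < X.shape[1] + 1:
            raise DataValidationError(f"need n >= k+2, got n={n}, k+1={X.shape[1]}")
        if len(self.snp_ids) != S.shape[1]:
            raise DataValidationError("snp_ids length must equal number of SNP columns")
        return self


@dataclass
class FitConfig:
    """Gradient-descent settings.

    ``step=None`` selects ``4 / ||X||_2^2``, the inverse Lipschitz constant of
    the logistic gradient, which guarantees monotone log-likelihood ascent.
    ``tol=0`` disables early stopping (fixed iteration count, mirroring a
    backend that cannot test convergence); ``tol>0`` stops once
    ``||X^T (y - p)||_2 <= tol``.
    """

    step: Optional[float] = None
    iters: int = 30
    tol: float = 0.0
    sigmoid_mode: Literal["exact", "lut"] = "exact"
    record_trace: bool = False

    def __post_init__(self) -> None:
        if self.step is not None and not self.step > 0:
            raise ValueError("step must be positive")
        if self.iters < 1:
            raise ValueError("iters must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.sigmoid_mode not in ("exact", "lut"):
            raise ValueError(f"unknown sigmoid_mode {self.sigmoid_mode!r}")


@dataclass
class GDIteration:
    """Per-iteration intermediates: linear predictor and the e/Delta bookkeeping."""

    u: np.ndarray
    e: np.ndarray
    delta: np.ndarray


@dataclass
class ModelState:
    beta: np.ndarray
    iterations_run: int
    grad_norm: float
    trace: list[GDIteration] = field(default_factory=list)


@dataclass
class SigmoidLUT:
    """Uniform table of sigmoid samples on ``[sigma_min, sigma_max]``.

    ``table[q] = sigma(sigma_min + (q/d) * (sigma_max - sigma_min))`` for
    ``q = 0..d``.  Lookup rounds the scaled argument to the nearest level
    (ties to even) and clamps, so out-of-range inputs saturate at the
    endpoint values.
    """

    sigma_min: float
    sigma_max: float
    d: int
    table: np.ndarray

    def __post_init__(self) -> None:
        if not self.sigma_min < self.sigma_max:
            raise ValueError("need sigma_min < sigma_max")
        if self.d < 1:
            raise ValueError("need at least d=1 levels")


def sigmoid_exact(x):
    """Numerically stable logistic function ``1/(1+exp(-x))``."""
    return expit(x)


def d_from_ring(N: int, cols: int) -> int:
    """Number of table levels ``floor(N/cols) - 1`` that fit in a ring of degree N.

    ``cols`` is the number of columns of X packed alongside each level
    (intercept included).
    """
    if N < 1 or cols < 1:
        raise ValueError("N and cols must be positive")
    return N // cols - 1

def build_sigmoid_lut(sigma_min: float, sigma_max: float, d: int) -> SigmoidLUT:
    if d < 1:
        raise ValueError("d must be >= 1")
    grid = sigma_min + (np.arange(d + 1) / d) * (sigma_max - sigma_min)
    return SigmoidLUT(sigma_min, sigma_max, d, expit(grid))


def lut_sigmoid(lut: SigmoidLUT, x):
    """Evaluate the table at the level nearest to ``x`` (round-half-even, clamped)."""
    t = (np.asarray(x, float) - lut.sigma_min) / (lut.sigma_max - lut.sigma_min) * lut.d
    q = np.clip(np.rint(t), 0, lut.d).astype(np.intp)
    out = lut.table[q]
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def _sigma(mode: str, lut: Optional[SigmoidLUT]):
    if mode == "exact":
        return sigmoid_exact
    if lut is None:
        raise ValueError("sigmoid_mode='lut' requires a SigmoidLUT")
    return lambda u: lut_sigmoid(lut, u)


def default_step(X: np.ndarray) -> float:
    """Largest step with guaranteed ascent: 4 / ||X||_2^2 (logistic Hessian bound)."""
    s = np.linalg.norm(X, 2)
    if s == 0:
        raise ValueError("X has zero spectral norm")
    return 4.0 / (s * s)


def fit_logistic_gd(
    data: Dataset, cfg: FitConfig, lut: Optional[SigmoidLUT] = None
) -> ModelState:
    """Fit beta by fixed-step gradient descent on the logistic log-likelihood.

    Initialisation is ``beta0_j = alpha * sum_i X_ij (y_i - 1/2)`` — the first
    gradient step from beta=0, where ``sigma(0)=1/2`` plays the role of the
    initial probabilities.  Each iteration computes ``u = X beta`` and applies
    ``beta <- beta + e - Delta`` with ``e = alpha X^T y`` and
    ``Delta = alpha X^T sigma*(u)``.
    """
    data.validate()
    X = np.asarray(data.X, float)
    y = np.asarray(data.y, float)
    alpha = cfg.step if cfg.step is not None else default_step(X)
    sigma = _sigma(cfg.sigmoid_mode, lut)

    beta = alpha * (X.T @ (y - 0.5))
    e = alpha * (X.T @ y)  # constant across iterations
    trace: list[GDIteration] = []
    grad_norm = np.inf
    it = 0
    for it in range(1, cfg.iters + 1):
        u = X @ beta
        if not np.all(np.isfinite(u)):
            raise DivergenceError(
                f"non-finite linear predictor at iteration {it}; reduce the step size"
            )
        p = sigma(u)
        grad = X.T @ (y - p)
        grad_norm = float(np.linalg.norm(grad))
        if cfg.tol > 0 and grad_norm <= cfg.tol:
            it -= 1
            break
        delta = alpha * (X.T @ p)
        beta = beta + e - delta
        if not np.all(np.isfinite(beta)):
            raise DivergenceError(
                f"non-finite coefficients at iteration {it}; reduce the step size"
            )
        if cfg.record_trace:
            trace.append(GDIteration(u=u, e=e, delta=delta))
    return ModelState(beta=beta, iterations_run=it, grad_norm=grad_norm, trace=trace)


def predict_probabilities(
    X: np.ndarray,
    beta: np.ndarray,
    sigmoid_mode: str = "exact",
    lut: Optional[SigmoidLUT] = None,
) -> np.ndarray:
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns, beta length {beta.shape[0]}"
        )
    return _sigma(sigmoid_mode, lut)(X @ beta)


def compute_weights(p: np.ndarray) -> np.ndarray:
    """Logistic variance weights ``w_i = p_i - p_i^2``, in [0, 1/4]."""
    p = np.asarray(p, float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return p - p * p


def log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Bernoulli log-likelihood at beta (stable via logaddexp)."""
    u = np.asarray(X, float) @ np.asarray(beta, float)
    return float(np.sum(np.asarray(y, float) * u - np.logaddexp(0.0, u)))
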