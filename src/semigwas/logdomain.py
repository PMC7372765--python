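"""Log-domain evaluation of the association statistic.

Division and square roots are expensive under approximate encrypted
arithmetic, so the final statistic ``t_j = num_j / sqrt(den_j)`` can instead
be assembled in the logarithmic domain:

    log|t_j| = log|num_j| - (1/2) log(den_j),

with ``log|.|`` replaced by a *smoothed* version that is quadratic inside a
small threshold ``th`` (removing the singularity at 0 so the function can be
approximated by a polynomial), and the smoothed function itself replaced by a
degree-8 even least-squares polynomial on the plausible input range.  The
sign of the numerator is carried separately, exactly; p-values depend only on
|t|, so they are unaffected.

The smoothing constants are forced by continuity and differentiability at
``x = th``:  ``a = 1/(2 th^2)`` and ``b = ln(th) - 1/2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np


@dataclass(frozen=True)
class SmoothedLogParams:
    """Quadratic-capped log-absolute-value: ln|x| outside th, a x^2 + b inside."""

    th: float
    a: float
    b: float


@dataclass
class PolyApprox:
    """Even least-squares polynomial approximation on [fit_lo, fit_hi].

    Coefficients are stored for the rescaled variable ``x / xscale`` (even
    powers 0, 2, ..., degree), which keeps the normal equations
    well-conditioned; ``max_error`` is the achieved sup-norm error on the fit
    grid.
    """

    degree: int
    coefficients: np.ndarray
    fit_lo: float
    fit_hi: float
    even: bool = True
    xscale: float = 1.0
    max_error: float = field(default=np.nan)

    def evaluate(self, x):
        t = (np.asarray(x, float) / self.xscale) ** 2
        acc = np.zeros_like(t)
        for c in self.coefficients[::-1]:  # Horner in x^2
            acc = acc * t + c
        return acc

    __call__ = evaluate


def smoothed_logabs_params(th: float) -> SmoothedLogParams:
    """Matching constants at x=th: value ln(th)=a th^2+b and slope 1/th = 2 a th."""
    if not 0 < th <= 1:
        raise ValueError("threshold th must lie in (0, 1]")
    a = 1.0 / (2.0 * th * th)
    b = math.log(th) - 0.5
    return SmoothedLogParams(th=th, a=a, b=b)


def smoothed_logabs(x, params: SmoothedLogParams):
    """ln|x| for |x| > th, else the matched quadratic a x^2 + b (even, continuous)."""
    x = np.asarray(x, float)
    ax = np.abs(x)
    out = np.where(
        ax > params.th,
        np.log(np.where(ax > params.th, ax, 1.0)),
        params.a * x * x + params.b,
    )
    return float(out) if out.ndim == 0 else out


def fit_logabs_poly(
    lo: float,
    hi: float,
    params: SmoothedLogParams,
    degree: int = 8,
    even: bool = True,
    grid_n: int = 4096,
) -> PolyApprox:
    """Least-squares even-polynomial fit of the smoothed log on a uniform grid.

    Degree 8 with even symmetry has 5 free coefficients (powers 0,2,4,6,8).
    The fit is done in the rescaled variable x/xscale with xscale =
    max(|lo|,|hi|) so the Vandermonde matrix stays well-conditioned; an
    ill-conditioned system still raises with a pointer to an orthogonal basis.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if not even:
        raise NotImplementedError("only the even (symmetric) basis is implemented")
    if degree % 2 != 0 or degree < 2:
        raise ValueError("degree must be a positive even integer")
    if grid_n < 10 * degree:
        raise ValueError("grid_n must be at least 10 * degree")
    x = np.linspace(lo, hi, grid_n)
    y = smoothed_logabs(x, params)
    xscale = max(abs(lo), abs(hi))
    t = (x / xscale) ** 2
    V = np.vander(t, degree // 2 + 1, increasing=True)
    cond = np.linalg.cond(V)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"normal equations ill-conditioned (cond={cond:.3g}); "
            "fit in an orthogonal (Chebyshev/Legendre) basis instead"
        )
    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    approx = PolyApprox(
        degree=degree, coefficients=coef, fit_lo=lo, fit_hi=hi, even=True,
        xscale=xscale,
    )
    approx.max_error = float(np.max(np.abs(approx.evaluate(x) - y)))
    return approx


LogTransform = Union[PolyApprox, SmoothedLogParams]


def _apply(transform: LogTransform, x):
    if isinstance(transform, PolyApprox):
        return transform.evaluate(x)
    if isinstance(transform, SmoothedLogParams):
        return smoothed_logabs(x, transform)
    raise TypeError(f"unsupported log transform {type(transform).__name__}")


def log_domain_stat(
    numerator: np.ndarray,
    denominator: np.ndarray,
    poly_num: LogTransform,
    poly_den: LogTransform,
) -> tuple[np.ndarray, np.ndarray]:
    """``log_stat = L(num) - (1/2) L(den)`` with the numerator sign kept exact.

    ``L`` is a :class:`PolyApprox` (the encrypted-friendly path) or
    :class:`SmoothedLogParams` (exact smoothed-log mode, for which
    ``exp(log_stat) = |t|`` exactly whenever |num| > th and den > th^2).
    Masked (NaN) entries propagate.  ``sign * exp(log_stat)`` reconstructs t.
    """
    num = np.asarray(numerator, float)
    den = np.asarray(denominator, float)
    if num.shape != den.shape:
        raise ValueError("numerator and denominator must have equal length")
    log_stat = _apply(poly_num, num) - 0.5 * _apply(poly_den, den)
    return log_stat, np.sign(num)


def centered_square_transform(s: np.ndarray, center: float = 0.0) -> np.ndarray:
    """Optional path taking s* (not squared): square then shift by a center.

    Exposed for pipelines that carry the un-squared denominator; the default
    scan already produces s*^2 directly, so this is off the main path.
    """
    s = np.asarray(s, float)
    return s * s - center
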