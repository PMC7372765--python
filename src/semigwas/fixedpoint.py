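"""Torus fixed-point scaling, range simulation and the quantized pipeline.

Encrypted torus-based backends represent every value as a fraction of the
unit circle R/Z; a real variable with engineering range [lo, hi] is embedded
by a scale factor so that the scaled magnitude stays inside the usable torus
fraction (1/4 by default — table-based function evaluation is antiperiodic,
which halves the usable range).  This module provides, in plain arithmetic:

* scale derivation from observed ranges (:func:`derive_scale`);
* quantization of scaled values to a dyadic grid ``2^-f`` with either modular
  ``wrap``, ``strict`` overflow errors, or plain rounding (``none``);
* a one-pass range simulation of the pipeline recording avg/stdev/min/max for
  the eight tracked intermediates;
* :func:`run_quantized`, the full scan with quantize/dequantize applied after
  each named intermediate, for measuring how fixed-point precision degrades
  the final statistics relative to the exact pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .core_model import (
    Dataset,
    FitConfig,
    ModelState,
    SigmoidLUT,
    compute_weights,
    fit_logistic_gd,
    predict_probabilities,
)
from .semiparallel_stats import (
    StatResult,
    compute_A,
    compute_gram,
    compute_tstat,
    invert_G_exact,
    invert_G_taylor,
    semiparallel_scan,
    stat_denominator,
    stat_numerator,
    tstat_to_pvalue,
)

#: The tracked intermediates, in pipeline order: fitted probabilities, logistic
#: weights, score numerator z*, Gram matrix, cross-product, score denominator,
#: the statistic and its p-value.
TRACKED_VARIABLES = ("p", "W", "z*", "G", "A", "s*2", "r_i", "p-value")


class FixedPointOverflowError(OverflowError):
    """Raised in strict mode when a scaled value leaves the torus budget."""


@dataclass(frozen=True)
class FixedPointSpec:
    """Embedding of one variable into torus fixed point.

    ``scale`` maps engineering units to torus units; ``frac_bits`` sets the
    grid ``2^-frac_bits``; ``torus_budget`` is the usable torus fraction
    (default 1/4, the antiperiodic half of the half-torus); ``overflow_policy``
    is ``wrap`` (reduce mod 1 into [-1/2, 1/2)), ``strict`` (raise) or
    ``none`` (round only, no modular reduction).
    """

    scale: float
    frac_bits: int = 20
    torus_budget: float = 0.25
    overflow_policy: str = "wrap"

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if not 0 < self.torus_budget <= 0.5:
            raise ValueError("torus_budget must lie in (0, 1/2]")
        if self.overflow_policy not in ("wrap", "strict", "none"):
            raise ValueError(f"unknown overflow_policy {self.overflow_policy!r}")


@dataclass
class RangeReport:
    variable: str
    avg: float
    stdev: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.avg <= self.max):
            raise ValueError("need min <= avg <= max")


def derive_scale(min_val: float, max_val: float, budget: float = 0.25) -> float:
    """Scale factor fitting [min_val, max_val] into +/- budget of the torus."""
    if not max_val > min_val:
        raise ValueError("need max_val > min_val")
    if not budget > 0:
        raise ValueError("budget must be positive")
    amp = max(abs(min_val), abs(max_val))
    if amp == 0:
        raise ValueError("zero-width range around 0 has no scale")
    return budget / amp


def packed_blocks(m: int, slots: int = 4096) -> int:
    """Ciphertext blocks needed to pack m SNP slots: ceil(m / slots)."""
    if m < 0 or slots < 1:
        raise ValueError("need m >= 0 and slots >= 1")
    return math.ceil(m / slots)


def quantize(x, spec: FixedPointSpec, name: str = "value"):
    """Scale to torus units and round to the dyadic grid (half-to-even)."""
    v = np.asarray(x, float) * spec.scale
    step = 2.0 ** spec.frac_bits
    g = np.round(v * step) / step
    if spec.overflow_policy == "strict":
        amax = float(np.max(np.abs(g), initial=0.0))
        if amax > spec.torus_budget + 2.0 ** (-spec.frac_bits - 1):
            raise FixedPointOverflowError(
                f"{name}: scaled magnitude {amax:.6g} exceeds torus budget "
                f"{spec.torus_budget}"
            )
    elif spec.overflow_policy == "wrap":
        g = np.mod(g + 0.5, 1.0) - 0.5
    return g


def dequantize(t, spec: FixedPointSpec):
    return np.asarray(t, float) / spec.scale


def quantize_dequantize(x, spec: FixedPointSpec, name: str = "value"):
    return dequantize(quantize(x, spec, name=name), spec)


def simulate_ranges(
    data: Dataset,
    cfg: Optional[FitConfig] = None,
    lut: Optional[SigmoidLUT] = None,
) -> list[RangeReport]:
    """Run the exact pipeline once and record ranges of the tracked variables.

    This is the plaintext simulation used to choose fixed-point scales: each
    report carries avg/stdev/min/max over all entries of that intermediate
    (degenerate NaN statistics excluded).
    """
    cfg = cfg or FitConfig()
    state = fit_logistic_gd(data, cfg, lut=lut)
    p = predict_probabilities(data.X, state.beta, cfg.sigmoid_mode, lut)
    w = compute_weights(p)
    G = compute_gram(data.X, w)
    A = compute_A(data.X, w, data.S)
    num = stat_numerator(data.y, p, data.S)
    den = stat_denominator(w, data.S, A, invert_G_exact(G), binary_S=not data.dosage)
    t, _ = compute_tstat(num, den, eps_den=1e-12 * data.n)
    pv = tstat_to_pvalue(t)
    arrays = {
        "p": p,
        "W": w,
        "z*": num,
        "G": G.ravel(),
        "A": A.ravel(),
        "s*2": den,
        "r_i": t,
        "p-value": pv,
    }
    reports = []
    for name in TRACKED_VARIABLES:
        a = arrays[name][np.isfinite(arrays[name])]
        reports.append(
            RangeReport(
                variable=name,
                avg=float(a.mean()),
                stdev=float(a.std()),
                min=float(a.min()),
                max=float(a.max()),
            )
        )
    return reports


def two_pass_specs(
    reports: Sequence[RangeReport],
    frac_bits: int = 20,
    budget: float = 0.25,
    margin: float = 2.0,
    overflow_policy: str = "wrap",
) -> dict[str, FixedPointSpec]:
    """Per-variable specs from observed ranges (the two-pass mode).

    ``margin`` widens each observed range before deriving the scale, the same
    safety headroom as widening a simulated sigmoid input range before fixing
    the table domain; it keeps small excursions of the quantized pipeline
    beyond the simulated extremes away from the wrap-around point.
    """
    if margin < 1:
        raise ValueError("margin must be >= 1")
    specs = {}
    for r in reports:
        amp = max(abs(r.min), abs(r.max))
        amp = amp if amp > 0 else 1.0
        specs[r.variable] = FixedPointSpec(
            scale=budget / (margin * amp),
            frac_bits=frac_bits,
            torus_budget=budget,
            overflow_policy=overflow_policy,
        )
    return specs


def uniform_specs(
    frac_bits: int,
    scale: float = 1.0,
    overflow_policy: str = "none",
    budget: float = 0.25,
) -> dict[str, FixedPointSpec]:
    """One identical spec for every tracked variable (fidelity experiments)."""
    spec = FixedPointSpec(
        scale=scale, frac_bits=frac_bits, torus_budget=budget,
        overflow_policy=overflow_policy,
    )
    return {name: spec for name in TRACKED_VARIABLES}


def check_overflow(
    reports: Sequence[RangeReport], specs: Mapping[str, FixedPointSpec]
) -> list[str]:
    """One warning per variable whose observed range leaves its torus budget."""
    warnings_out = []
    for r in reports:
        spec = specs.get(r.variable)
        if spec is None:
            continue
        amp = max(abs(r.min), abs(r.max)) * spec.scale
        if amp > spec.torus_budget:
            warnings_out.append(
                f"{r.variable}: scaled magnitude {amp:.6g} exceeds torus budget "
                f"{spec.torus_budget:.6g}"
            )
    return warnings_out


def run_quantized(
    data: Dataset,
    cfg: Optional[FitConfig] = None,
    specs: Optional[Mapping[str, FixedPointSpec]] = None,
    lut: Optional[SigmoidLUT] = None,
    ginv_mode: str = "exact",
    taylor_order: int = 2,
    state: Optional[ModelState] = None,
) -> StatResult:
    """Full scan with quantize/dequantize applied after each named intermediate.

    Quantization is applied at ciphertext granularity — after each tracked
    intermediate is formed, never inside the matrix products that form it.
    ``specs`` must cover every name in :data:`TRACKED_VARIABLES`.  A
    precomputed ``ModelState`` may be passed to reuse a fit across precision
    sweeps (the fit itself depends only on the sigmoid mode, not on f).
    """
    cfg = cfg or FitConfig()
    if specs is None:
        specs = two_pass_specs(simulate_ranges(data, cfg, lut=lut))
    missing = [v for v in TRACKED_VARIABLES if v not in specs]
    if missing:
        raise ValueError(f"specs missing variables: {missing}")
    if state is None:
        state = fit_logistic_gd(data, cfg, lut=lut)
    p = predict_probabilities(data.X, state.beta, cfg.sigmoid_mode, lut)
    p = quantize_dequantize(p, specs["p"], name="p")
    w = compute_weights(np.clip(p, 0.0, 1.0))
    w = quantize_dequantize(w, specs["W"], name="W")
    G = compute_gram(data.X, np.clip(w, 0.0, None))
    G = quantize_dequantize(G, specs["G"], name="G")
    A = compute_A(data.X, w, data.S)
    A = quantize_dequantize(A, specs["A"], name="A")
    if ginv_mode == "exact":
        Ginv = invert_G_exact(G)
    elif ginv_mode == "taylor":
        Ginv = invert_G_taylor(G, taylor_order)
    else:
        raise ValueError(f"unknown ginv_mode {ginv_mode!r}")
    num = stat_numerator(data.y, p, data.S)
    num = quantize_dequantize(num, specs["z*"], name="z*")
    den = stat_denominator(
        w, data.S, A, Ginv, binary_S=not data.dosage, check_negative=False
    )
    den = quantize_dequantize(den, specs["s*2"], name="s*2")
    np.clip(den, 0.0, None, out=den)
    t, mask = compute_tstat(num, den, eps_den=1e-12 * data.n)
    finite = ~mask
    t[finite] = quantize_dequantize(t[finite], specs["r_i"], name="r_i")
    pv = tstat_to_pvalue(t)
    pv[finite] = np.clip(
        quantize_dequantize(pv[finite], specs["p-value"], name="p-value"), 0.0, 1.0
    )
    return StatResult(
        snp_ids=list(data.snp_ids),
        numerator=num,
        denominator=den,
        tstat=t,
        pvalue=pv,
        sign=np.sign(num),
        masked=mask,
    )


def compare_quantized_vs_exact(
    data: Dataset,
    cfg: Optional[FitConfig] = None,
    specs: Optional[Mapping[str, FixedPointSpec]] = None,
    lut: Optional[SigmoidLUT] = None,
) -> dict[str, float]:
    """Agreement between the quantized (possibly LUT) scan and the exact one.

    The reference is the exact-arithmetic, exact-sigmoid pipeline; returns the
    maximum absolute statistic deviation and the Pearson correlation over
    unmasked SNPs.
    """
    exact_cfg = replace(cfg or FitConfig(), sigmoid_mode="exact")
    exact, _ = semiparallel_scan(data, exact_cfg)
    quant = run_quantized(data, cfg, specs=specs, lut=lut)
    ok = ~(exact.masked | quant.masked)
    diff = float(np.max(np.abs(quant.tstat[ok] - exact.tstat[ok])))
    r = float(np.corrcoef(quant.tstat[ok], exact.tstat[ok])[0, 1])
    return {"max_abs_diff": diff, "pearson_r": r, "n_compared": float(ok.sum())}
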