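"""Synthetic genotype/phenotype generator.

Emulates the statistical shape of a small case-control GWAS panel: binary
genotype columns drawn independently as Bernoulli(MAF), standard-normal
covariates with an intercept, and a logistic outcome whose linear predictor
combines covariate effects and any declared causal SNP effects.  The
benchmark-shaped preset (:func:`idash_like`) produces n=245 patients,
m=10643 SNPs and k=3 covariates.

The default intercept of -0.2 anchors the baseline prevalence near 0.45.
Not emulated: linkage disequilibrium between columns, population structure,
and diploid 0/1/2 dosages (genotypes are presence/absence bits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit

from .core_model import Dataset

MafLike = Union[float, tuple, np.ndarray, list]


@dataclass
class SynthConfig:
    n: int = 245
    m: int = 1000
    k: int = 3
    #: scalar rate, (lo, hi) range to sample uniformly, or per-SNP vector
    maf: MafLike = (0.05, 0.5)
    #: true effects, length k+1 including the intercept; None -> default anchor
    beta_cov: Optional[np.ndarray] = None
    #: (snp index, effect size) pairs added to the linear predictor
    causal: Sequence[tuple[int, float]] = field(default_factory=tuple)
    seed: int = 0
    #: test-only escape hatch: permit maf 0 (monomorphic columns)
    allow_zero_maf: bool = False

    def resolved_beta_cov(self) -> np.ndarray:
        if self.beta_cov is not None:
            b = np.asarray(self.beta_cov, float)
            if b.shape != (self.k + 1,):
                raise ValueError(f"beta_cov must have length k+1 = {self.k + 1}")
            return b
        b = np.full(self.k + 1, 0.3)
        b[0] = -0.2  # baseline prevalence sigma(-0.2) ~ 0.45
        b[2::2] *= -1.0
        return b


def _resolve_maf(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    lo_bound = 0.0 if cfg.allow_zero_maf else np.nextafter(0.0, 1.0)
    if isinstance(cfg.maf, tuple):
        lo, hi = cfg.maf
        if not (lo_bound <= lo <= hi <= 0.5):
            raise ValueError("maf range must satisfy 0 < lo <= hi <= 0.5")
        maf = rng.uniform(lo, hi, size=cfg.m)
    else:
        maf = np.broadcast_to(np.asarray(cfg.maf, float), (cfg.m,)).copy()
        if np.any(maf < lo_bound) or np.any(maf > 0.5):
            raise ValueError("maf values must lie in (0, 0.5]")
    return maf


def generate_dataset(cfg: SynthConfig) -> Dataset:
    """Draw a dataset, fully determined by ``cfg.seed``.

    X = [1 | k standard-normal columns]; S_ij ~ Bernoulli(maf_j) independent;
    eta = X beta_cov + sum of causal effects; y_i ~ Bernoulli(sigma(eta_i)).
    """
    if cfg.n < cfg.k + 2 or cfg.m < 1 or cfg.k < 0:
        raise ValueError("invalid dimensions: need n >= k+2, m >= 1, k >= 0")
    for idx, _ in cfg.causal:
        if not 0 <= idx < cfg.m:
            raise ValueError(f"causal SNP index {idx} out of range [0, {cfg.m})")
    rng = np.random.default_rng(cfg.seed)
    maf = _resolve_maf(cfg, rng)
    X = np.ones((cfg.n, cfg.k + 1))
    X[:, 1:] = rng.standard_normal((cfg.n, cfg.k))
    S = rng.binomial(1, maf, size=(cfg.n, cfg.m)).astype(float)
    eta = X @ cfg.resolved_beta_cov()
    for idx, effect in cfg.causal:
        eta = eta + effect * S[:, idx]
    y = rng.binomial(1, expit(eta)).astype(float)
    width = max(5, len(str(cfg.m)))
    snp_ids = [f"snp{j:0{width}d}" for j in range(cfg.m)]
    return Dataset(X=X, y=y, S=S, snp_ids=snp_ids).validate()


def idash_like(seed: int, n: int = 245, m: int = 10643, k: int = 3) -> Dataset:
    """Benchmark-shaped panel: 245 patients x 10643 SNPs x 3 covariates, null SNPs."""
    return generate_dataset(SynthConfig(n=n, m=m, k=k, maf=(0.05, 0.5), seed=seed))
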