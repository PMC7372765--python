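# Methods

## Model and procedure

The scan tests each binary genotype column for association with a binary
outcome under a logistic model with covariate adjustment.  It is a one-step
(score/Wald-type) approximation: the covariate-only model is fitted once and
each SNP is scored against the fitted weights without refitting, so the
statistic is not identical to the Wald z of a full per-SNP refit — the tests
assert correlation ≥ 0.99 against per-SNP GLM refits on null data, not
equality.

Two algebraically equivalent routes are implemented and tested against each
other:

* **Projection oracle.**  Working response `z = Xβ + (y−p)/w`, change of
  variable by `√W`, explicit orthogonal projection of `√W z` and `√W S` onto
  the complement of the span of `√W X` (via QR).  Quadratic in `n`; used as
  the reference.
* **Simplified pipeline.**  `numerator = (y−p)ᵀS` and
  `s*² = colsums(W·S) − colsums(A ⊙ G⁻¹A)` with `G = XᵀWX`, `A = XᵀWS`.  The
  numerator identity relies on the covariate gradient vanishing, so it is
  exact only in the limit of convergence; the test suite verifies that the
  discrepancy shrinks monotonically as the gradient-norm tolerance tightens
  through {1e−2, 1e−4, 1e−6, 1e−10} and is below 1e−6 relative at 1e−10.

p-values are two-sided standard normal in |t| (equivalently χ²₁ in t²), the
standard reference distribution for a GWAS Wald score.  The statistic's sign
is kept alongside the log-domain form, which by itself only determines |t|;
p-values depend on |t| only.

### Gradient descent

Fixed-step gradient ascent with `β⁰ = α·Xᵀ(y − 1/2)` (the first step from
zero) and update `β ← β + e − Δ`, `e = αXᵀy`, `Δ = αXᵀσ(Xβ)` — the
added/subtracted bookkeeping form used by accumulator-style backends, equal
to `β + αXᵀ(y − σ(Xβ))` to machine precision (property-tested).

* `step` (α): default `4/‖X‖₂²`.  The logistic gradient is Lipschitz with
  constant `‖X‖₂²/4`, so this is the classical `1/L` step with guaranteed
  monotone log-likelihood ascent (tested).  User-overridable.
* `iters`: default 30 with `tol = 0` — a fixed iteration count mirrors a
  deployment that cannot test convergence.  `tol > 0` enables gradient-norm
  early stopping and is used everywhere a converged fit is needed.
* Divergence (non-finite β or Xβ, possible with an oversized manual step)
  raises a named error with the iteration index instead of propagating NaN.

### LUT sigmoid

The table stores `d+1` bare sigmoid samples on `[σ_min, σ_max]` (defaults
−4…4, `d = 2047 = ⌊8192/4⌋ − 1` via `d_from_ring`); index = round-half-even
of the affinely mapped argument, clamped to the table (out-of-range inputs
saturate).  Sup error inside the range is bounded by half the grid step times
the maximal slope 1/4: `(σ_max−σ_min)/(2d)·(1/4)` ≈ 4.89e−4 at d = 2047
(verified by dense scan).  Step size and covariate values are applied in the
update, not folded into the table — algebraically identical to fusing them,
and it keeps one table for all covariates.  "Columns of X" always means
`k+1` (intercept included); `d_from_ring` takes the column count explicitly
to avoid the off-by-one ambiguity.

### Gram inversion

`invert_G_exact` uses Cholesky (raises on non-SPD input).  `invert_G_taylor`
implements the Neumann series around `G = I/4`: with `eps = 4G − I`,
`G⁻¹ ≈ 4·Σ_{t≤order}(−eps)ᵗ`.  This is the convergent form of the series;
the convergence condition is spectral radius of `eps` below 1, checked and
warned about (not fatal — partial sums are still returned).  Order 0 gives
`4I`, a usable approximation whenever the fitted weights sit near their
maximum 1/4 and the covariates are near-orthonormal.

## Fixed point

Torus backends hold values as fractions of [−1/2, 1/2); table-based function
evaluation is antiperiodic, restricting usable values to a quarter of the
torus.  Hence `torus_budget` defaults to 1/4 (configurable to 1/2 for
variables that never pass through a table).  `derive_scale(lo, hi, budget) =
budget / max(|lo|, |hi|)`; for the widened sigmoid input range −4…4 this
gives the scale 1/16.

Quantization maps `x → round(x·scale·2^f)/2^f` with round-half-even, then
applies the overflow policy: `wrap` (exact mod-1 reduction into [−1/2, 1/2),
the torus-faithful default), `strict` (error naming the variable), or `none`
(rounding only).  `none` exists for fidelity experiments that need scale 1 on
variables whose engineering range exceeds the torus — at f = 53 the grid is
finer than double precision for |x| < 1 and the quantized pipeline reproduces
the exact one to 1e−9, which wrap would destroy by reducing mod 1.

Quantization is applied **after each named intermediate** (p, W, G, A,
numerator, denominator, statistic, p-value) and never inside the matrix
products that form them — emulating ciphertext-level granularity, where a
packed intermediate is one object.

Scales come from a **two-pass** mode: `simulate_ranges` runs the exact
pipeline once and records avg/stdev/min/max of the eight tracked variables
(the range table a deployment would derive by plaintext simulation);
`two_pass_specs` then sets `scale = budget/(margin·maxabs)` per variable.
`margin` defaults to 2 — the same kind of headroom as widening an observed
sigmoid input range before freezing the table domain — so small excursions of
the quantized pipeline beyond the simulated extremes cannot reach the
wrap-around point.  A static mode (user-supplied specs) is also accepted.
`check_overflow` flags any variable whose observed range exceeds its budget.

The quantized-vs-exact comparison (`compare_quantized_vs_exact`) uses the
exact-arithmetic, exact-sigmoid scan as the reference, so it measures the
combined effect of the LUT and the fixed-point grid; `run_quantized` against
a same-sigmoid exact run isolates the grid effect alone.  With two-pass
scales and f = 20 the statistic correlation is ≥ 0.99 on synthetic panels
(in practice ≈ 1 − 1e−10).

## Log-domain statistic

`log|t| = L(numerator) − ½·L(s*²)` with the sign of the numerator carried
separately and exactly.  `L` is `smoothed_logabs`: `ln|x|` for `|x| > th`,
else `a·x² + b` with `a = 1/(2th²)`, `b = ln(th) − 1/2` — the unique
constants making the function continuous and differentiable at `x = th`
(domain of th: (0, 1]).  For polynomial evaluation, `L` is replaced by a
degree-8 even least-squares fit on a uniform grid (default 4096 nodes) over
the plausible range of each input; the fit is performed in `u = (x/xscale)²`
(degree 4 in u), which keeps the Vandermonde system well-conditioned and
makes evenness structural.  Uniform grid rather than Chebyshev nodes: the
target is a least-squares fit, and node choice is a free design point; an
ill-conditioned system raises with a pointer to an orthogonal-basis fit.

Accuracy is limited by the dip of the smoothed log near zero: an even
degree-8 polynomial cannot track `ln|x|` down to `th = 0.05` over a range of
±35, so the sup fit error is a few nats and concentrated near zero, while
entries away from the dip are reconstructed to a fraction of a nat (median
≈ 0.35 nats on the reference panel).  The tests assert exactly the bound the
construction guarantees — log-scale error ≤ combined sup fit error, rank
preservation for pairs separated by more than twice that — plus the exact
identity `exp(log_stat) = |t|` when `L` is the un-approximated smoothed log.
Raising `th` or narrowing the fit range tightens the fit; `th` is exposed as
a parameter (default 0.05) since any adaptation rule is dataset-dependent.

The "square-and-center" path (consuming un-squared s* values) is exposed as
an optional transform (`centered_square_transform`); the default pipeline
already carries s*² so it is off the main path, and both centering
interpretations (subtract a configured center) are available through its
`center` argument.

## Synthetic data

`generate_dataset` draws `X = [1 | k N(0,1) columns]`, independent
`S_ij ~ Bernoulli(maf_j)` (maf scalar, uniform range, or per-SNP vector in
(0, 0.5]; the default range 0.05–0.5 keeps columns polymorphic at n = 245),
and `y ~ Bernoulli(σ(Xβ_cov + Σ γ·S_causal))`.  Default covariate effects are
±0.3 with intercept −0.2, anchoring baseline prevalence near 0.45.
Everything is a deterministic function of the seed.

Not emulated: linkage disequilibrium, population stratification, diploid
0/1/2 genotypes (a `dosage` flag in the scan supports 0/1/2 input matrices,
which disables the `S⊙S = S` shortcut).  Passing tests on these panels
therefore demonstrates numerical and statistical correctness of the
pipeline under its stated model, not robustness to confounding structure in
real cohorts.

### Problem sizes in the checks

The acceptance-style checks run on panels of 300 patients × 500 SNPs
(oracle/fixed-point/log-domain agreement), 300 × 2000 (null calibration,
binomial band 0.05 ± 3·√(0.05·0.95/2000)), and 100 replicates of
1000 × 201 with one causal SNP of effect 1.0 (detection = beating the median
null p-value).  These sizes give tight Monte-Carlo bands while keeping the
whole suite fast; the scan itself is vectorized and handles the
245 × 10643 benchmark shape directly (`idash_like`).

## Degenerate inputs and numerical choices

* Monomorphic or covariate-collinear SNPs have `s*² ≈ 0`; they are masked
  (NaN statistic, `masked` flag) at threshold `eps_den = 1e−12·n`, never
  silently dropped — output row order always equals input SNP order.
* `s*²` is a squared projection norm, so a negative value beyond
  `1e−9·max(colsums WS)` with an exact inverse raises; with a Taylor inverse
  small negatives are clipped to zero and masked.
* W is always a vector (the diagonal), never a dense matrix.
* Weighted Gram matrices are explicitly symmetrized after formation.
* All LUT/quantization rounding is round-half-even.
* Patient alignment in file ingestion is by explicit id join; VCF genotypes
  are binarized as "any ALT allele present", with missing calls a named
  error unless an imputation value is given.

## Known limitations

* The statistic is a one-step approximation; for SNPs with large effects it
  deviates from a full refit (by design — that is what makes it one matrix
  product instead of m fits).
* The Taylor inversion path is only sensible when `‖4G − I‖ < 1`; strongly
  unbalanced covariates require the Cholesky path.
* The log-domain polynomial path trades accuracy near |numerator| ≈ 0 for
  evaluability; rankings among near-zero statistics are not preserved there.
* No multiple-testing correction is applied; outputs are raw p-values.
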