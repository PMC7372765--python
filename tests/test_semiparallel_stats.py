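import numpy as np
import pytest

from semigwas.core_model import Dataset, FitConfig, fit_logistic_gd
from semigwas.semiparallel_stats import (
    SingularMatrixError,
    compute_A,
    compute_gram,
    compute_tstat,
    invert_G_exact,
    invert_G_taylor,
    oracle_semiparallel,
    semiparallel_scan,
    stat_denominator,
    stat_numerator,
    tstat_to_pvalue,
)
from semigwas.synthetic_data import SynthConfig, generate_dataset
from tests.conftest import CONVERGED


def brute_force_gram(X, w):
    k = X.shape[1]
    G = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            for i in range(X.shape[0]):
                G[a, b] += X[i, a] * w[i] * X[i, b]
    return G


class TestGramAndCross:
    def test_intercept_only_constant_weights(self):
        G = compute_gram(np.ones((4, 1)), np.full(4, 0.25))
        np.testing.assert_allclose(G, [[1.0]], atol=0)

    def test_unit_weights_reduce_to_xtx(self, rng):
        X = rng.standard_normal((6, 3))
        np.testing.assert_allclose(compute_gram(X, np.ones(6)), X.T @ X, atol=1e-12)

    def test_matches_triple_loop(self, rng):
        X = rng.standard_normal((5, 3))
        w = rng.uniform(0, 0.25, 5)
        np.testing.assert_allclose(compute_gram(X, w), brute_force_gram(X, w),
                                   atol=1e-12)
        S = rng.integers(0, 2, (5, 4)).astype(float)
        A = compute_A(X, w, S)
        A_brute = np.einsum("ia,i,ij->aj", X, w, S)
        np.testing.assert_allclose(A, A_brute, atol=1e-12)

    def test_zero_genotypes_give_zero_cross_product(self, rng):
        X = rng.standard_normal((5, 2))
        A = compute_A(X, np.full(5, 0.2), np.zeros((5, 3)))
        np.testing.assert_array_equal(A, 0.0)

    def test_intercept_only_cross_product_closed_form(self, rng):
        S = rng.integers(0, 2, (8, 3)).astype(float)
        A = compute_A(np.ones((8, 1)), np.full(8, 0.21), S)
        np.testing.assert_allclose(A[0], 0.21 * S.sum(axis=0), atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_gram(rng.standard_normal((5, 2)), np.ones(4))


class TestGramInversion:
    def test_quarter_identity_is_fixed_point_of_series(self):
        G = 0.25 * np.eye(3)
        for order in (0, 1, 5):
            np.testing.assert_allclose(invert_G_taylor(G, order), 4 * np.eye(3),
                                       atol=0)

    def test_order_zero_is_four_identity(self, rng):
        G = 0.25 * np.eye(4) + 0.01 * rng.standard_normal((4, 4))
        np.testing.assert_allclose(invert_G_taylor(G, 0), 4 * np.eye(4), atol=0)

    def test_series_error_decreases_monotonically(self, rng):
        E = rng.standard_normal((4, 4)) * 0.01
        G = 0.25 * np.eye(4) + 0.5 * (E + E.T)
        exact = np.linalg.inv(G)
        errs = [np.linalg.norm(invert_G_taylor(G, t) - exact) for t in range(6)]
        assert np.all(np.diff(errs) < 0)
        assert errs[-1] < 1e-3 * errs[0]

    def test_divergent_series_warns(self):
        with pytest.warns(RuntimeWarning, match="diverges"):
            invert_G_taylor(np.eye(2), 3)  # 4G - I = 3I, radius 3

    def test_cholesky_inverse_known_values(self):
        np.testing.assert_allclose(invert_G_exact(np.eye(3)), np.eye(3), atol=0)
        G = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(
            invert_G_exact(G), np.array([[2, -1], [-1, 2]]) / 3, atol=1e-14
        )

    def test_cholesky_inverse_random_spd(self, rng):
        B = rng.standard_normal((5, 5))
        G = B @ B.T + 5 * np.eye(5)
        np.testing.assert_allclose(G @ invert_G_exact(G), np.eye(5), atol=1e-10)

    def test_non_positive_definite_raises(self):
        with pytest.raises(SingularMatrixError):
            invert_G_exact(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestStatPieces:
    def test_numerator_vanishes_at_perfect_fit(self, rng):
        y = rng.uniform(0.1, 0.9, 10)
        S = rng.integers(0, 2, (10, 4)).astype(float)
        np.testing.assert_allclose(stat_numerator(y, y, S), 0.0, atol=0)

    def test_numerator_hand_values(self):
        y = np.array([1.0, 0.0])
        p = np.array([0.5, 0.5])
        S = np.array([[1.0, 1.0], [0.0, 1.0]])
        np.testing.assert_allclose(stat_numerator(y, p, S), [0.5, 0.0], atol=0)

    def test_denominator_zero_for_monomorphic_column(self, rng):
        X = np.ones((6, 1))
        w = np.full(6, 0.25)
        S = np.zeros((6, 1))
        A = compute_A(X, w, S)
        den = stat_denominator(w, S, A, invert_G_exact(compute_gram(X, w)))
        np.testing.assert_allclose(den, 0.0, atol=1e-12)

    def test_denominator_intercept_only_closed_form(self, rng):
        # projecting a binary column onto the constant vector:
        # s*2 = w c (1 - c/n) for constant weight w and column sum c
        n, w0 = 12, 0.21
        S = rng.integers(0, 2, (n, 5)).astype(float)
        X = np.ones((n, 1))
        w = np.full(n, w0)
        A = compute_A(X, w, S)
        den = stat_denominator(w, S, A, invert_G_exact(compute_gram(X, w)))
        c = S.sum(axis=0)
        np.testing.assert_allclose(den, w0 * c * (1 - c / n), atol=1e-10)

    def test_denominator_upper_bound_and_nonnegativity(self, small_data, small_state):
        res, _ = semiparallel_scan(small_data, CONVERGED, state=small_state)
        from semigwas.core_model import compute_weights, predict_probabilities

        w = compute_weights(predict_probabilities(small_data.X, small_state.beta))
        assert np.all(res.denominator >= -1e-10)
        assert np.all(res.denominator <= small_data.S.T @ w + 1e-10)

    def test_dosage_mode_squares_explicitly(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        w = rng.uniform(0.1, 0.25, n)
        S = rng.integers(0, 3, (n, 6)).astype(float)
        A = compute_A(X, w, S)
        Ginv = invert_G_exact(compute_gram(X, w))
        den = stat_denominator(w, S, A, Ginv, binary_S=False)
        lead = (S * S).T @ w
        np.testing.assert_allclose(den, lead - np.einsum("ij,ij->j", A, Ginv @ A),
                                   atol=1e-10)

    @pytest.mark.parametrize("num,den,expected", [(0.0, 5.0, 0.0), (1.0, 4.0, 0.5)])
    def test_tstat_arithmetic(self, num, den, expected):
        t, mask = compute_tstat(np.array([num]), np.array([den]))
        assert not mask[0]
        assert t[0] == pytest.approx(expected, abs=0)

    def test_tstat_masks_degenerate_denominators(self):
        t, mask = compute_tstat(np.array([1.0, 2.0]), np.array([0.0, 4.0]))
        assert mask.tolist() == [True, False]
        assert np.isnan(t[0]) and t[1] == 1.0

    def test_negative_denominator_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_tstat(np.array([1.0]), np.array([-0.5]))

    def test_pvalue_known_quantiles(self):
        np.testing.assert_allclose(
            tstat_to_pvalue(np.array([0.0, 1.959964])), [1.0, 0.05], atol=5e-7
        )

    def test_pvalue_strictly_decreasing_in_abs_t(self, rng):
        t = np.sort(np.abs(rng.standard_normal(50)))
        p = tstat_to_pvalue(t)
        assert np.all(np.diff(p) <= 0)
        assert np.all((p >= 0) & (p <= 1))


class TestOracleEquivalence:
    def test_projector_properties(self, small_data, small_state):
        _, state = oracle_semiparallel(small_data, small_state.beta)
        P = state.projector
        np.testing.assert_allclose(P @ P, P, atol=1e-10)
        np.testing.assert_allclose(P, P.T, atol=1e-10)
        # residual working response is orthogonal to the covariate span
        from semigwas.core_model import compute_weights, predict_probabilities

        w = compute_weights(predict_probabilities(small_data.X, small_state.beta))
        Xp = np.sqrt(w)[:, None] * small_data.X
        np.testing.assert_allclose(Xp.T @ state.zstar_prime, 0.0, atol=1e-8)

    def test_simplified_matches_projection_oracle_at_convergence(
        self, small_data, small_state
    ):
        res, _ = semiparallel_scan(small_data, CONVERGED, state=small_state)
        oracle, _ = oracle_semiparallel(small_data, small_state.beta)
        num_scale = np.max(np.abs(oracle.numerator))
        den_scale = np.max(oracle.denominator)
        assert np.max(np.abs(res.numerator - oracle.numerator)) / num_scale < 1e-6
        assert np.max(np.abs(res.denominator - oracle.denominator)) / den_scale < 1e-6

    def test_discrepancy_shrinks_with_convergence_tolerance(self, small_data):
        gaps = []
        for tol in (1e-2, 1e-4, 1e-6, 1e-10):
            state = fit_logistic_gd(small_data, FitConfig(iters=200_000, tol=tol))
            res, _ = semiparallel_scan(small_data, state=state)
            oracle, _ = oracle_semiparallel(small_data, state.beta)
            gaps.append(np.max(np.abs(res.numerator - oracle.numerator)))
        assert np.all(np.diff(gaps) < 0)

    def test_basis_invariance_of_statistics(self, small_data, small_state):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        data2 = Dataset(X=small_data.X @ M, y=small_data.y, S=small_data.S,
                        snp_ids=small_data.snp_ids)
        r1, _ = semiparallel_scan(small_data, CONVERGED)
        r2, _ = semiparallel_scan(data2, CONVERGED)
        np.testing.assert_allclose(r1.numerator, r2.numerator, atol=1e-7)
        np.testing.assert_allclose(r1.denominator, r2.denominator, atol=1e-7)
        np.testing.assert_allclose(r1.tstat, r2.tstat, atol=1e-7)

    def test_score_tracks_per_snp_wald_refits(self):
        sm = pytest.importorskip("statsmodels.api")
        data = generate_dataset(SynthConfig(n=300, m=40, k=2, seed=21))
        res, _ = semiparallel_scan(data, CONVERGED)
        zref = []
        for j in range(data.m):
            Xj = np.column_stack([data.X, data.S[:, j]])
            fit = sm.GLM(data.y, Xj, family=sm.families.Binomial()).fit()
            zref.append(fit.params[-1] / fit.bse[-1])
        r = np.corrcoef(res.tstat, zref)[0, 1]
        assert r > 0.99
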