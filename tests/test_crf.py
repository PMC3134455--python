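"""Joint model, conditionals, pseudo-likelihood derivatives, fitting, Gibbs."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm

from crfgwas.crf import (
    conditional_prob,
    coupling_offsets,
    fit_pseudolikelihood,
    gibbs_sample_crf,
    log_partition_bruteforce,
    neg_log_pseudolikelihood,
    pl_gradient,
    pl_hessian,
    pl_per_individual_scores,
    robust_variance,
    score_outer_product,
    unnormalized_log_joint,
)
from tests.conftest import random_instance


def exact_log_joint(y, X, w, A):
    """Independent term-by-term re-summation of the exponent."""
    s = 2.0 * np.asarray(y, float) - 1.0
    total = 0.0
    for i in range(len(s)):
        total += s[i] * float(np.dot(X[i], w))
    for i in range(len(s)):
        for j in range(i + 1, len(s)):
            total += A[i, j] * s[i] * s[j]
    return total


def exact_log_partition(X, w, A):
    n = X.shape[0]
    vals = [
        exact_log_joint(np.array(cfg), X, w, A)
        for cfg in itertools.product([0, 1], repeat=n)
    ]
    m = max(vals)
    return m + np.log(sum(np.exp(v - m) for v in vals))


class TestJointAndPartition:
    def test_zero_couplings_zero_weights_give_zero(self, rng):
        n = 5
        X = rng.standard_normal((n, 2))
        A = np.eye(n)
        for _ in range(3):
            y = rng.integers(0, 2, n)
            assert unnormalized_log_joint(y, X, np.zeros(2), A * 0) == 0.0

    def test_single_edge_sign_follows_agreement(self):
        X = np.zeros((2, 1))
        A = np.array([[1.0, 0.7], [0.7, 1.0]])
        w = np.zeros(1)
        assert unnormalized_log_joint([1, 1], X, w, A) == pytest.approx(0.7)
        assert unnormalized_log_joint([0, 0], X, w, A) == pytest.approx(0.7)
        assert unnormalized_log_joint([1, 0], X, w, A) == pytest.approx(-0.7)

    def test_matches_term_by_term_oracle(self, rng):
        X, w, A, y = random_instance(rng, 6)
        assert unnormalized_log_joint(y, X, w, A) == pytest.approx(
            exact_log_joint(y, X, w, A), abs=1e-12
        )

    def test_partition_factorizes_without_couplings(self, rng):
        n = 6
        X = rng.standard_normal((n, 2))
        w = rng.normal(0, 0.8, 2)
        h = X @ w
        expect = float(np.sum(np.log(np.exp(h) + np.exp(-h))))
        assert log_partition_bruteforce(X, w, np.zeros((n, n))) == pytest.approx(expect)

    def test_uniform_model_counts_states(self):
        X = np.zeros((3, 1))
        assert log_partition_bruteforce(X, np.zeros(1), np.zeros((3, 3))) == pytest.approx(np.log(8))

    def test_matches_enumeration_oracle(self, rng):
        X, w, A, _ = random_instance(rng, 8)
        assert log_partition_bruteforce(X, w, A) == pytest.approx(
            exact_log_partition(X, w, A), abs=1e-10
        )

    def test_enumeration_guard(self):
        X = np.zeros((21, 1))
        with pytest.raises(ValueError, match="refus"):
            log_partition_bruteforce(X, np.zeros(1), np.zeros((21, 21)))


class TestConditionals:
    def test_symmetric_model_gives_half(self, rng):
        n = 5
        X = rng.standard_normal((n, 2))
        y = rng.integers(0, 2, n)
        for i in range(n):
            assert conditional_prob(i, y, X, np.zeros(2), np.zeros((n, n))) == pytest.approx(0.5)

    def test_agrees_with_exact_joint_ratio(self, rng):
        """P(y_i=1 | y_-i) from the closed form vs brute-force joint, <= 1e-10."""
        for n in (4, 7, 10):
            X, w, A, y = random_instance(rng, n)
            logZ = log_partition_bruteforce(X, w, A)
            for i in range(n):
                y1, y0 = y.copy(), y.copy()
                y1[i], y0[i] = 1, 0
                p1 = np.exp(unnormalized_log_joint(y1, X, w, A) - logZ)
                p0 = np.exp(unnormalized_log_joint(y0, X, w, A) - logZ)
                exact = p1 / (p1 + p0)
                assert conditional_prob(i, y, X, w, A) == pytest.approx(exact, abs=1e-10)

    def test_monotone_in_neighbour_field(self, rng):
        n = 4
        X = rng.standard_normal((n, 1))
        y = np.array([1, 0, 1, 0])
        probs = []
        for scale in (0.0, 0.5, 1.0, 2.0):
            A = np.full((n, n), 0.3 * scale)
            np.fill_diagonal(A, 1.0)
            probs.append(conditional_prob(0, y, X, np.zeros(1), A))
        s = 2.0 * y - 1.0
        direction = np.sign(s[1] + s[2] + s[3])
        diffs = np.diff(probs) * (direction if direction != 0 else 1.0)
        assert (diffs >= -1e-12).all() or (diffs <= 1e-12).all()


class TestPseudolikelihood:
    def test_null_model_value_is_n_log2(self, rng):
        n = 9
        X = rng.standard_normal((n, 2))
        y = rng.integers(0, 2, n)
        val = neg_log_pseudolikelihood(np.zeros(2), y, X, np.zeros(n))
        assert val == pytest.approx(n * np.log(2))

    def test_equals_sum_of_conditional_logs(self, rng):
        X, w, A, y = random_instance(rng, 8)
        offsets = coupling_offsets(A, y)
        expect = -sum(
            np.log(conditional_prob(i, y, X, w, A)) if y[i] == 1
            else np.log(1.0 - conditional_prob(i, y, X, w, A))
            for i in range(8)
        )
        got = neg_log_pseudolikelihood(w, y, X, offsets)
        assert got == pytest.approx(expect, abs=1e-10)
        assert got >= 0.0

    def test_midpoint_convexity(self, rng):
        X, _, A, y = random_instance(rng, 10, p=3)
        offsets = coupling_offsets(A, y)
        for _ in range(10):
            w1 = rng.normal(0, 1, 3)
            w2 = rng.normal(0, 1, 3)
            mid = neg_log_pseudolikelihood((w1 + w2) / 2, y, X, offsets)
            avg = (neg_log_pseudolikelihood(w1, y, X, offsets)
                   + neg_log_pseudolikelihood(w2, y, X, offsets)) / 2
            assert mid <= avg + 1e-10


def finite_diff_grad(f, w, h=1e-6):
    g = np.zeros_like(w)
    for k in range(w.size):
        e = np.zeros_like(w)
        e[k] = h
        g[k] = (f(w + e) - f(w - e)) / (2 * h)
    return g


class TestDerivatives:
    def test_gradient_matches_central_differences(self, rng):
        X, w, A, y = random_instance(rng, 15, p=3)
        offsets = coupling_offsets(A, y)
        g = pl_gradient(w, y, X, offsets)
        fd = finite_diff_grad(lambda v: neg_log_pseudolikelihood(v, y, X, offsets), w)
        np.testing.assert_allclose(g, fd, rtol=1e-6, atol=1e-8)

    def test_hessian_matches_gradient_differences(self, rng):
        X, w, A, y = random_instance(rng, 15, p=3)
        offsets = coupling_offsets(A, y)
        H = pl_hessian(w, y, X, offsets)
        h = 1e-6
        fd = np.zeros_like(H)
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            fd[:, k] = (pl_gradient(w + e, y, X, offsets)
                        - pl_gradient(w - e, y, X, offsets)) / (2 * h)
        np.testing.assert_allclose(H, fd, rtol=1e-5, atol=1e-7)

    def test_hessian_psd_and_vanishes_when_saturated(self, rng):
        X, w, A, y = random_instance(rng, 12, p=2)
        offsets = coupling_offsets(A, y)
        H = pl_hessian(w, y, X, offsets)
        assert np.linalg.eigvalsh(H).min() >= -1e-10
        H_sat = pl_hessian(w * 1e4, y, X, offsets)
        assert np.abs(H_sat).max() < 1e-6

    def test_zero_coupling_score_is_doubled_logistic_score(self, rng):
        n = 30
        X = rng.standard_normal((n, 2))
        y = rng.integers(0, 2, n)
        w = rng.normal(0, 0.3, 2)
        g = pl_gradient(w, y, X, np.zeros(n))
        # logistic score at coefficient beta = 2w, times the chain factor 2
        from scipy.special import expit
        logistic_score = (expit(X @ (2 * w)) - y) @ X
        np.testing.assert_allclose(g, 2.0 * logistic_score, atol=1e-10)

    def test_score_outer_product_identities(self, rng):
        X, w, A, y = random_instance(rng, 10, p=3)
        offsets = coupling_offsets(A, y)
        G = pl_per_individual_scores(w, y, X, offsets)
        B = score_outer_product(w, y, X, offsets)
        np.testing.assert_allclose(B, B.T, atol=1e-12)
        assert np.linalg.eigvalsh(B).min() >= -1e-10
        assert np.trace(B) == pytest.approx(sum(np.dot(gi, gi) for gi in G))
        np.testing.assert_allclose(G.sum(axis=0), pl_gradient(w, y, X, offsets), atol=1e-12)


class TestRobustVariance:
    def test_information_equality_case(self, rng):
        M = rng.standard_normal((3, 3))
        H = M @ M.T + np.eye(3)
        sigma, ok = robust_variance(H, H)
        assert ok
        np.testing.assert_allclose(sigma, np.linalg.inv(H), atol=1e-10)

    def test_identity_bread(self, rng):
        M = rng.standard_normal((3, 3))
        B = M @ M.T
        sigma, _ = robust_variance(np.eye(3), B)
        np.testing.assert_allclose(sigma, B, atol=1e-12)

    def test_2x2_cofactor_oracle(self, rng):
        a, b, c = 2.0, 0.3, 1.5
        H = np.array([[a, b], [b, c]])
        M = rng.standard_normal((2, 2))
        B = M @ M.T
        det = a * c - b * b
        Hinv = np.array([[c, -b], [-b, a]]) / det
        sigma, ok = robust_variance(H, B)
        assert ok
        np.testing.assert_allclose(sigma, Hinv @ B @ Hinv, atol=1e-12)

    def test_singular_bread_flagged(self):
        H = np.array([[1.0, 1.0], [1.0, 1.0]])
        _, ok = robust_variance(H, np.eye(2))
        assert not ok


class TestFit:
    def test_reduces_to_logistic_regression_without_couplings(self, rng):
        n = 120
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        beta_true = np.array([0.2, -0.6, 0.4])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(int)
        fit = fit_pseudolikelihood(y, X, np.zeros(n))
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(2 * fit.weights, glm.params, atol=1e-6)
        robust = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        np.testing.assert_allclose(4 * fit.sandwich, robust.cov_params(), atol=1e-6)

    def test_initialization_independent_optimum(self, rng):
        X, _, A, y = random_instance(rng, 40, p=3, coupling_sd=0.05)
        offsets = coupling_offsets(A, y)
        fits = [
            fit_pseudolikelihood(y, X, offsets, w0=rng.normal(0, 2, 3))
            for _ in range(4)
        ]
        for f in fits[1:]:
            np.testing.assert_allclose(f.weights, fits[0].weights, atol=1e-6)

    def test_gradient_descent_reaches_newton_optimum(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.integers(0, 2, n)
        newton = fit_pseudolikelihood(y, X, np.zeros(n))
        gd = fit_pseudolikelihood(y, X, np.zeros(n), optimizer="gd",
                                  eta=0.01, tol=1e-8, max_iter=20000)
        assert gd.converged
        np.testing.assert_allclose(gd.weights, newton.weights, atol=1e-5)

    def test_collinear_column_dropped_and_reported(self, rng):
        n = 40
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = rng.integers(0, 2, n)
        fit = fit_pseudolikelihood(y, X, np.zeros(n))
        assert fit.dropped_columns == (2,)
        assert np.isnan(fit.weights[2])


class TestGibbs:
    def test_independent_null_marginals(self):
        n = 20
        X = np.zeros((n, 1))
        rng = np.random.default_rng(3)
        draws = np.array([
            gibbs_sample_crf(X, np.zeros(1), np.zeros((n, n)), 2, rng)
            for _ in range(500)
        ])
        freq = draws.mean()
        assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(500 * n)

    def test_deterministic_given_seed(self, rng):
        X, w, A, _ = random_instance(rng, 15)
        a = gibbs_sample_crf(X, w, A, 30, seed=7)
        b = gibbs_sample_crf(X, w, A, 30, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_small_n_frequencies_match_exact_distribution(self, rng):
        n = 5
        X = rng.standard_normal((n, 1))
        w = np.array([0.4])
        A = rng.normal(0, 0.2, (n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        logZ = log_partition_bruteforce(X, w, A)
        exact = np.zeros(2 ** n)
        for idx, cfg in enumerate(itertools.product([0, 1], repeat=n)):
            exact[idx] = np.exp(unnormalized_log_joint(np.array(cfg), X, w, A) - logZ)
        g = np.random.default_rng(11)
        counts = np.zeros(2 ** n)
        y = gibbs_sample_crf(X, w, A, 20, g)
        for _ in range(20000):
            y = gibbs_sample_crf(X, w, A, 2, g, y0=y)
            idx = int("".join(str(int(v)) for v in y), 2)
            counts[idx] += 1
        emp = counts / counts.sum()
        assert np.abs(emp - exact).max() < 0.015

    def test_positive_couplings_increase_concordance(self):
        n = 30
        X = np.zeros((n, 1))
        strong = np.full((n, n), 1.5 / n)
        np.fill_diagonal(strong, 1.0)

        def concordance(A, seed):
            rng = np.random.default_rng(seed)
            vals = []
            for _ in range(200):
                y = gibbs_sample_crf(X, np.zeros(1), A, 10, rng)
                s = 2.0 * y - 1.0
                vals.append(np.mean(np.outer(s, s)[~np.eye(n, dtype=bool)]))
            return np.mean(vals)

        assert concordance(strong, 5) > concordance(np.zeros((n, n)), 5) + 0.05
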