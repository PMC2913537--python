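"""Scoring checks against independent numerical oracles.

The BGe score is verified against direct numerical integration over the
normal-Wishart parameters (a quadrature oracle that never touches the
closed-form code path); the BDe score against explicit gamma/beta-function
arithmetic.
"""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import betaln, gammaln, roots_legendre
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

import nsdbn as nd
from nsdbn.scoring import (bde_local_score, bge_local_score,
                           posterior_predictive_local_score)


# ---------------------------------------------------------------------------
# quadrature oracles for the BGe marginal
# ---------------------------------------------------------------------------

def _quad_marginal_1d(x, v, alpha_sub, t0=1.0, mu0=0.0):
    """m(x) for a single variable by 2-d quadrature over (mu, w):
    w ~ Gamma(alpha_sub/2, rate t0/2), mu | w ~ N(mu0, 1/(v w))."""

    def integrand(mu, w):
        lik = np.prod(norm.pdf(x, mu, 1.0 / np.sqrt(w)))
        return (lik * norm.pdf(mu, mu0, 1.0 / np.sqrt(v * w))
                * gamma_dist.pdf(w, alpha_sub / 2.0, scale=2.0 / t0))

    val, _ = integrate.dblquad(integrand, 1e-9, 80.0, -15.0, 15.0,
                               epsabs=1e-13, epsrel=1e-11)
    return np.log(val)


def _quad_marginal_2d(x, v, alpha_sub, n_nodes_grid=90, w_hi=45.0):
    """m(X) for an M x 2 data matrix by tensor quadrature over the 2 x 2
    Wishart precision (mu integrated analytically as a Gaussian convolution).

    Given W, the stacked data are Gaussian with covariance
    (I_M + J_M / v) kron W^{-1}; the prior is Wishart(alpha_sub, I).
    Parametrised as (w11, w22, rho) with w12 = rho sqrt(w11 w22).
    """
    x = np.asarray(x, float)
    M, l = x.shape
    assert l == 2
    A = np.eye(M) + np.ones((M, M))
    Ainv = np.linalg.inv(A)
    sign, logdetA = np.linalg.slogdet(A)

    nodes, weights = roots_legendre(n_nodes_grid)
    w_nodes = 0.5 * w_hi * (nodes + 1.0)
    w_wts = 0.5 * w_hi * weights
    r_nodes = nodes.copy()
    r_wts = weights.copy()

    W11, W22, RHO = np.meshgrid(w_nodes, w_nodes, r_nodes, indexing="ij")
    w12 = RHO * np.sqrt(W11 * W22)
    Wg = np.stack([np.stack([W11, w12], axis=-1),
                   np.stack([w12, W22], axis=-1)], axis=-2)
    Wg = Wg.reshape(-1, 2, 2)
    jac = np.sqrt(W11 * W22).ravel()
    logdetW = np.log(W11 * W22 * (1.0 - RHO ** 2)).ravel()

    # Gaussian likelihood of the stacked data given W
    Q = np.einsum("mi,gij,nj->gmn", x, Wg, x)
    qf = np.einsum("gmn,nm->g", Q, Ainv)
    loglik = (-(M * l / 2.0) * np.log(2.0 * np.pi)
              - 0.5 * (l * logdetA - M * logdetW) - 0.5 * qf)

    # Wishart(alpha_sub, scale I) log pdf on 2 x 2 matrices
    a = alpha_sub
    log_norm = (a * l / 2.0) * np.log(2.0) + (l * (l - 1) / 4.0) * np.log(np.pi) \
        + gammaln(a / 2.0) + gammaln((a - 1) / 2.0)
    logwish = ((a - l - 1) / 2.0) * logdetW - 0.5 * (W11 + W22).ravel() \
        - log_norm

    wts = (w_wts[:, None, None] * w_wts[None, :, None]
           * r_wts[None, None, :]).ravel()
    return np.log(np.sum(wts * jac * np.exp(loglik + logwish)))


class TestBGeOracle:
    def test_no_parent_family_matches_quadrature(self):
        hyper = nd.BGeHyper(n_nodes=2)           # alpha = 4, v = 1, T0 = I
        x = np.array([0.3, -1.1, 0.7])
        got = bge_local_score(x, np.empty((3, 0)), hyper, 0, ())
        want = _quad_marginal_1d(x, v=1.0, alpha_sub=4.0 - 2 + 1)
        assert got == pytest.approx(want, abs=1e-4)

    @pytest.mark.parametrize("n_obs", [3, 6])
    def test_one_parent_family_matches_quadrature(self, n_obs, rng):
        hyper = nd.BGeHyper(n_nodes=2)
        child = rng.standard_normal(n_obs) * 0.8
        parent = rng.standard_normal((n_obs, 1)) * 0.8
        got = bge_local_score(child, parent, hyper, 1, (0,))
        pair = np.column_stack([child, parent])
        log_joint = _quad_marginal_2d(pair, v=1.0, alpha_sub=4.0)
        log_par = _quad_marginal_1d(parent.ravel(), v=1.0, alpha_sub=3.0)
        assert got == pytest.approx(log_joint - log_par, abs=1e-4)


class TestBDe:
    def test_matches_beta_function_oracle(self):
        # binary node, no parents, counts (3, 1), ESS 1
        child = np.array([2, 2, 1, 2])
        got = bde_local_score(child, np.empty((4, 0)), nd.BDeHyper(1.0), r=2)
        want = betaln(0.5 + 1, 0.5 + 3) - betaln(0.5, 0.5)
        assert got == pytest.approx(want, abs=1e-10)

    def test_with_parent_matches_gamma_arithmetic(self, rng):
        child = rng.integers(1, 3, 12)
        parent = rng.integers(1, 3, (12, 1))
        got = bde_local_score(child, parent, nd.BDeHyper(1.0), r=2)
        # independent tally: q = 2 configs, cell pseudocount 1/4, row 1/2
        want = 0.0
        for cfg in (1, 2):
            mask = parent.ravel() == cfg
            n1 = int(np.sum(child[mask] == 1))
            n2 = int(np.sum(child[mask] == 2))
            want += gammaln(0.5) - gammaln(0.5 + n1 + n2)
            want += gammaln(0.25 + n1) - gammaln(0.25)
            want += gammaln(0.25 + n2) - gammaln(0.25)
        assert got == pytest.approx(want, abs=1e-10)

    def test_order_permutation_invariance(self, rng):
        child = rng.integers(1, 4, 10)
        parent = rng.integers(1, 4, (10, 2))
        perm = rng.permutation(10)
        a = bde_local_score(child, parent, nd.BDeHyper(), r=3)
        b = bde_local_score(child[perm], parent[perm], nd.BDeHyper(), r=3)
        assert a == pytest.approx(b, abs=1e-12)

    def test_unseen_category_rejected(self):
        with pytest.raises(ValueError):
            bde_local_score(np.array([1, 3]), np.empty((2, 0)),
                            nd.BDeHyper(), r=2)


class TestConventionsAndErrors:
    def test_empty_family_scores_psi_one(self):
        hyper = nd.BGeHyper(n_nodes=3)
        assert bge_local_score(np.empty(0), np.empty((0, 1)), hyper,
                               0, (1,)) == 0.0
        assert bde_local_score(np.empty(0), np.empty((0, 0)),
                               nd.BDeHyper(), r=2) == 0.0

    def test_non_positive_definite_prior_rejected(self):
        with pytest.raises(ValueError):
            nd.BGeHyper(n_nodes=2,
                        prior_precision_scale=np.array([[1.0, 2.0],
                                                        [2.0, 1.0]]))

    def test_dimension_mismatch_rejected(self, rng):
        hyper = nd.BGeHyper(n_nodes=2)
        with pytest.raises(ValueError):
            bge_local_score(rng.standard_normal(4),
                            rng.standard_normal((3, 1)), hyper, 0, (1,))

    def test_self_loop_family_needs_diagonal_prior(self, rng):
        t0 = np.array([[1.0, 0.3], [0.3, 1.0]])
        hyper = nd.BGeHyper(n_nodes=2, prior_precision_scale=t0)
        with pytest.raises(ValueError):
            bge_local_score(rng.standard_normal(4),
                            rng.standard_normal((4, 1)), hyper, 0, (0,))


class TestChainRuleAndAdditivity:
    def test_chain_rule_over_compartment_splits(self, small_continuous):
        """Psi(A u B) = Psi(A) Psi(B | posterior after A) for any split."""
        sc = nd.BGeScorer(small_continuous)
        times = (2, 3, 4, 5, 6, 7)
        for cut in (1, 2, 4):
            a, b = times[:cut], times[cut:]
            full = sc.family_log_score(1, (0, 1), times)
            part_a = sc.family_log_score(1, (0, 1), a)
            ca, pa = sc.family_arrays(1, (0, 1), a)
            cb, pb = sc.family_arrays(1, (0, 1), b)

            def fn(c, p):
                return bge_local_score(c, p, sc.hyper, 1, (0, 1))

            pred = posterior_predictive_local_score(ca, pa, cb, pb, fn)
            assert full == pytest.approx(part_a + pred, rel=1e-9)

    def test_two_parent_marginalisation_consistency(self, rng):
        """The joint subset marginal expands identically along either
        chain-rule ordering of a two-parent family."""
        hyper = nd.BGeHyper(n_nodes=3)
        x = rng.standard_normal((5, 3))
        from nsdbn.scoring import _bge_subset_marginal
        joint = _bge_subset_marginal(x, [0, 1, 2], hyper)
        # chain via node 0 first
        a = _bge_subset_marginal(x[:, [0]], [0], hyper)
        b = _bge_subset_marginal(x[:, [0, 1]], [0, 1], hyper) - a
        c = joint - (a + b)
        # chain via node 2 first
        a2 = _bge_subset_marginal(x[:, [2]], [2], hyper)
        b2 = _bge_subset_marginal(x[:, [1, 2]], [1, 2], hyper) - a2
        c2 = joint - (a2 + b2)
        assert a + b + c == pytest.approx(a2 + b2 + c2, rel=1e-12)

    def test_segment_marginal_worked_split(self, rng):
        """m = 11, one changepoint between t6 and t7: the total is the sum
        of the two per-segment scores."""
        data = nd.TimeSeriesDataset(rng.standard_normal((2, 11)), ["X", "Y"])
        graph = nd.Graph(2, frozenset({(0, 1)}), 3, True)
        sc = nd.BGeScorer(data)
        alloc = nd.allocation_from_changepoints([6.5], 11)
        total = nd.segment_log_marginal(sc, graph, alloc)
        left = (sc.family_log_score(0, (), (2, 3, 4, 5, 6))
                + sc.family_log_score(1, (0,), (2, 3, 4, 5, 6)))
        right = (sc.family_log_score(0, (), (7, 8, 9, 10, 11))
                 + sc.family_log_score(1, (0,), (7, 8, 9, 10, 11)))
        assert total == pytest.approx(left + right, rel=1e-12)

    def test_single_component_equals_homogeneous_score(self, small_discrete):
        graph = nd.Graph(2, frozenset({(0, 1), (1, 1)}), 3, True)
        sc = nd.BDeScorer(small_discrete)
        alloc = np.ones(small_discrete.m - 1, dtype=int)
        total = nd.segment_log_marginal(sc, graph, alloc)
        times = tuple(range(2, small_discrete.m + 1))
        direct = (sc.family_log_score(0, (), times)
                  + sc.family_log_score(1, (0, 1), times))
        assert total == pytest.approx(direct, rel=1e-12)

    def test_cache_free_oracle(self, small_continuous, rng):
        """Cached segment scores equal a from-scratch recomputation that
        bypasses the scorer cache entirely."""
        graph = nd.Graph(2, frozenset({(0, 0), (0, 1)}), 3, True)
        sc = nd.BGeScorer(small_continuous)
        alloc = np.array([1, 1, 2, 2, 1, 3, 3])  # free-style allocation
        cached = nd.segment_log_marginal(sc, graph, alloc)
        cached_again = nd.segment_log_marginal(sc, graph, alloc)

        vals = small_continuous.values
        oracle = 0.0
        for k in (1, 2, 3):
            ts = np.nonzero(alloc == k)[0] + 2
            for node, parents in ((0, (0,)), (1, (0,))):
                child = vals[node, ts - 1]
                pmat = vals[list(parents)][:, ts - 2].T
                oracle += bge_local_score(child, pmat, sc.hyper, node,
                                          parents)
        assert cached == pytest.approx(oracle, rel=1e-12)
        assert cached_again == cached

    def test_likelihood_equivalence_on_shared_rows(self, rng):
        """Scoring the same two-column family data in either conditioning
        order gives the same joint marginal."""
        hyper = nd.BGeHyper(n_nodes=2)
        a = rng.standard_normal(6)
        b = rng.standard_normal(6)
        ab = (bge_local_score(a, b.reshape(-1, 1), hyper, 0, (1,))
              + bge_local_score(b, np.empty((6, 0)), hyper, 1, ()))
        ba = (bge_local_score(b, a.reshape(-1, 1), hyper, 1, (0,))
              + bge_local_score(a, np.empty((6, 0)), hyper, 0, ()))
        assert ab == pytest.approx(ba, rel=1e-10)


class TestPosteriorPredictive:
    def test_empty_train_reduces_to_prior_marginal(self, rng):
        hyper = nd.BGeHyper(n_nodes=2)
        test_c = rng.standard_normal(4)
        test_p = rng.standard_normal((4, 1))

        def fn(c, p):
            return bge_local_score(c, p, hyper, 0, (1,))

        pred = posterior_predictive_local_score(
            np.empty(0), np.empty((0, 1)), test_c, test_p, fn)
        assert pred == pytest.approx(fn(test_c, test_p), rel=1e-12)

    def test_bde_matches_sequential_prediction_oracle(self):
        """The BDe predictive equals the sequential product of categorical
        posterior-predictive probabilities over the test observations."""
        hyper = nd.BDeHyper(1.0)
        train = np.array([1, 2, 2, 1, 2])
        test = np.array([2, 1, 2, 2])

        def fn(c, p):
            return bde_local_score(c, p, hyper, r=2)

        got = posterior_predictive_local_score(
            train, np.empty((5, 0)), test, np.empty((4, 0)), fn)
        # sequential oracle: P(x) = (alpha_x + n_x) / (alpha_0 + n)
        counts = {1: int(np.sum(train == 1)), 2: int(np.sum(train == 2))}
        n = len(train)
        want = 0.0
        for x in test:
            want += np.log((0.5 + counts[int(x)]) / (1.0 + n))
            counts[int(x)] += 1
            n += 1
        assert got == pytest.approx(want, abs=1e-10)
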