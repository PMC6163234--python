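"""Gaussian-mixture EM: densities, E/M steps, likelihood, fitting, oracles."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from sitsense.errors import InsufficientDataError, NumericalDegeneracyError
from sitsense.gmm import (GaussianMixtureEM, GMMModel,
                          Responsibilities, assign_clusters, em_fit,
                          gaussian_density, log_likelihood, m_step,
                          model_from_dict, model_to_dict, responsibilities)


def two_blob_data(rng, n=200, m1=(0.0, 0.0), m2=(10.0, 10.0), sd=1.0):
    half = n // 2
    X = np.vstack([rng.normal(m1, sd, size=(half, 2)),
                   rng.normal(m2, sd, size=(n - half, 2))])
    y = np.array([0] * half + [1] * (n - half))
    return X, y


class TestDensity:
    def test_standard_normal_mode(self):
        assert gaussian_density([0.0], [0.0], [[1.0]]) == pytest.approx(
            1.0 / math.sqrt(2 * math.pi), rel=1e-12)

    @pytest.mark.parametrize("d", [1, 2, 5])
    def test_identity_covariance_at_mean(self, d):
        mu = np.zeros(d)
        assert gaussian_density(mu, mu, np.eye(d)) == pytest.approx(
            (2 * math.pi) ** (-d / 2), rel=1e-12)

    def test_integrates_to_one_by_quadrature(self, rng):
        """2-d density integrated over a wide grid sums to 1 (oracle)."""
        mu = rng.normal(size=2)
        A = rng.normal(size=(2, 2))
        cov = A @ A.T + 0.5 * np.eye(2)
        lim = 6 * math.sqrt(np.max(np.diag(cov)))
        xs = np.linspace(mu[0] - lim, mu[0] + lim, 201)
        ys = np.linspace(mu[1] - lim, mu[1] + lim, 201)
        dx, dy = xs[1] - xs[0], ys[1] - ys[0]
        total = sum(gaussian_density([x, y], mu, cov) for x in xs for y in ys)
        assert total * dx * dy == pytest.approx(1.0, abs=1e-3)

    def test_irreparably_degenerate_covariance_raises(self):
        with pytest.raises(NumericalDegeneracyError):
            gaussian_density([0.0, 0.0], [0.0, 0.0],
                             [[1.0, 0.0], [0.0, -5.0]], reg=1e-6)


def simple_model(k=2, d=1):
    if k == 1:
        return GMMModel(np.array([1.0]), np.zeros((1, d)),
                        np.repeat(np.eye(d)[None], 1, axis=0))
    return GMMModel(np.array([0.5, 0.5]), np.array([[-1.0], [1.0]]),
                    np.ones((2, 1, 1)))


class TestResponsibilities:
    def test_symmetric_point_splits_evenly(self):
        r = responsibilities(np.array([[0.0]]), simple_model()).matrix
        assert r[0] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_single_component_all_ones(self):
        r = responsibilities(np.array([[0.3], [7.0]]), simple_model(k=1)).matrix
        assert np.all(r == 1.0)

    def test_matches_scalar_bayes_oracle(self):
        """3-point, k=2 hand case against direct scalar Bayes arithmetic."""
        model = GMMModel(np.array([0.3, 0.7]), np.array([[0.0], [2.0]]),
                         np.array([[[1.0]], [[4.0]]]))
        X = np.array([[-1.0], [0.5], [3.0]])

        def phi(x, mu, var):
            return math.exp(-0.5 * (x - mu) ** 2 / var) / math.sqrt(2 * math.pi * var)

        got = responsibilities(X, model, reg=0.0).matrix
        for j, (x,) in enumerate(X):
            n1, n2 = 0.3 * phi(x, 0.0, 1.0), 0.7 * phi(x, 2.0, 4.0)
            assert got[j] == pytest.approx([n1 / (n1 + n2), n2 / (n1 + n2)],
                                           abs=1e-12)

    def test_rows_sum_to_one(self, rng):
        X = rng.normal(size=(40, 2))
        model = GMMModel(np.array([0.2, 0.8]), rng.normal(size=(2, 2)),
                         np.repeat(np.eye(2)[None], 2, axis=0))
        r = responsibilities(X, model).matrix
        assert np.allclose(r.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            Responsibilities(np.array([[0.6, 0.6]]))


class TestMStep:
    def test_k1_recovers_mle_moments(self, rng):
        X = rng.normal(size=(30, 3))
        resp = Responsibilities(np.ones((30, 1)))
        model = m_step(X, resp, reg=1e-6)
        assert model.means[0] == pytest.approx(X.mean(axis=0), abs=1e-12)
        mle_cov = np.cov(X, rowvar=False, bias=True) + 1e-6 * np.eye(3)
        assert model.covariances[0] == pytest.approx(mle_cov, abs=1e-10)

    def test_hard_responsibilities_plain_cluster_means(self, rng):
        X = rng.normal(size=(20, 2))
        hard = np.zeros((20, 2))
        hard[:12, 0] = 1.0
        hard[12:, 1] = 1.0
        model = m_step(X, Responsibilities(hard))
        assert model.means[0] == pytest.approx(X[:12].mean(axis=0), abs=1e-12)
        assert model.means[1] == pytest.approx(X[12:].mean(axis=0), abs=1e-12)
        assert model.weights == pytest.approx([0.6, 0.4], abs=1e-12)

    def test_matches_naive_loop_oracle(self, rng):
        """Random responsibilities on 10 points vs loop-based update formulas."""
        X = rng.normal(size=(10, 2))
        R = rng.dirichlet(np.ones(3), size=10)
        model = m_step(X, Responsibilities(R), reg=0.0)
        for i in range(3):
            mass = sum(R[j, i] for j in range(10))
            mu = sum(R[j, i] * X[j] for j in range(10)) / mass
            cov = sum(R[j, i] * np.outer(X[j] - mu, X[j] - mu)
                      for j in range(10)) / mass
            assert model.means[i] == pytest.approx(mu, abs=1e-12)
            assert model.covariances[i] == pytest.approx(cov, abs=1e-12)
            assert model.weights[i] == pytest.approx(mass / 10, abs=1e-12)

    def test_collapsed_component_error_mode(self, rng):
        X = rng.normal(size=(10, 1))
        R = np.column_stack([np.ones(10), np.zeros(10)])
        with pytest.raises(NumericalDegeneracyError):
            m_step(X, Responsibilities(R), on_collapse="error")


class TestLogLikelihood:
    def test_single_point_single_component(self):
        model = simple_model(k=1)
        x = np.array([[0.7]])
        assert log_likelihood(x, model, reg=0.0) == pytest.approx(
            math.log(gaussian_density([0.7], [0.0], [[1.0]], reg=0.0)), abs=1e-12)

    def test_duplicated_data_doubles_ll(self, rng):
        X = rng.normal(size=(15, 2))
        model = GMMModel(np.array([0.4, 0.6]), rng.normal(size=(2, 2)),
                         np.repeat(np.eye(2)[None], 2, axis=0))
        ll = log_likelihood(X, model)
        assert log_likelihood(np.vstack([X, X]), model) == pytest.approx(
            2 * ll, rel=1e-12)

    def test_matches_per_point_summation_oracle(self, rng):
        X = rng.normal(size=(8, 2))
        model = GMMModel(np.array([0.25, 0.75]), rng.normal(size=(2, 2)),
                         np.repeat(np.eye(2)[None] * 1.5, 2, axis=0))
        direct = sum(math.log(
            0.25 * gaussian_density(x, model.means[0], model.covariances[0], reg=0.0)
            + 0.75 * gaussian_density(x, model.means[1], model.covariances[1], reg=0.0))
            for x in X)
        assert log_likelihood(X, model, reg=0.0) == pytest.approx(direct, rel=1e-12)


class TestAssign:
    def test_argmax_and_tie_break(self):
        r = Responsibilities(np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]]))
        assert assign_clusters(r).tolist() == [0, 0, 1]

    def test_matches_naive_loop(self, rng):
        R = rng.dirichlet(np.ones(4), size=25)
        got = assign_clusters(Responsibilities(R))
        for j in range(25):
            best = max(range(4), key=lambda i: (R[j, i], -i))
            assert got[j] == best


class TestEMFit:
    def test_k1_converges_to_closed_form(self, rng):
        X = rng.normal(size=(50, 2))
        model, resp, trace = em_fit(X, k=1, seed=0)
        assert trace.n_iter <= 2
        assert model.means[0] == pytest.approx(X.mean(axis=0), abs=1e-10)
        mle = np.cov(X, rowvar=False, bias=True) + 1e-6 * np.eye(2)
        assert model.covariances[0] == pytest.approx(mle, abs=1e-8)

    def test_parameter_recovery_two_blobs(self, rng):
        X, y = two_blob_data(rng, n=200)
        model, resp, trace = em_fit(X, k=2, seed=7)
        order = np.argsort(model.means[:, 0])
        assert np.linalg.norm(model.means[order[0]] - [0, 0]) < 0.3
        assert np.linalg.norm(model.means[order[1]] - [10, 10]) < 0.3
        assert abs(model.weights[0] - 0.5) < 0.1
        assert adjusted_rand_score(y, assign_clusters(resp)) == 1.0

    def test_ll_monotone_and_normalized_invariants(self, rng):
        X, _ = two_blob_data(rng, n=120, m2=(4.0, 4.0))
        model, resp, trace = em_fit(X, k=2, seed=3)
        ll = trace.log_likelihoods
        assert all(b - a >= -1e-8 for a, b in zip(ll, ll[1:]))
        assert abs(model.weights.sum() - 1.0) < 1e-12
        assert np.allclose(resp.matrix.sum(axis=1), 1.0, atol=1e-12)
        for cov in model.covariances:
            assert np.min(np.linalg.eigvalsh(cov)) >= 1e-7

    def test_deterministic_given_seed(self, rng):
        X, _ = two_blob_data(rng, n=80)
        m1, r1, t1 = em_fit(X, k=2, seed=11)
        m2, r2, t2 = em_fit(X, k=2, seed=11)
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(r1.matrix, r2.matrix)
        assert t1.log_likelihoods == t2.log_likelihoods

    def test_permutation_of_components_preserves_ll_and_partition(self, rng):
        X, _ = two_blob_data(rng, n=100)
        model, resp, _ = em_fit(X, k=2, seed=5)
        perm = GMMModel(model.weights[::-1].copy(), model.means[::-1].copy(),
                        model.covariances[::-1].copy())
        assert log_likelihood(X, perm) == pytest.approx(
            log_likelihood(X, model), rel=1e-12)
        a = assign_clusters(responsibilities(X, model))
        b = assign_clusters(responsibilities(X, perm))
        assert adjusted_rand_score(a, b) == 1.0

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(InsufficientDataError):
            em_fit(rng.normal(size=(2, 2)), k=2)

    def test_matches_reference_em_with_identical_init(self, rng):
        """Converged fit agrees with an established EM implementation
        started from the same initial parameters."""
        X, _ = two_blob_data(rng, n=300, m2=(8.0, 8.0))
        k = 2
        init_means = np.array([[1.0, 1.0], [7.0, 7.0]])
        init_cov = np.cov(X, rowvar=False) + 1e-6 * np.eye(2)
        init = GMMModel(np.full(k, 0.5), init_means,
                        np.repeat(init_cov[None], k, axis=0))

        model = init
        for _ in range(500):
            resp = responsibilities(X, model)
            model = m_step(X, resp)
            if _ > 1 and abs(log_likelihood(X, model) - prev) < 1e-12:
                break
            prev = log_likelihood(X, model)

        ref = GaussianMixture(n_components=k, weights_init=np.full(k, 0.5),
                              means_init=init_means,
                              precisions_init=np.repeat(
                                  np.linalg.inv(init_cov)[None], k, axis=0),
                              reg_covar=1e-6, tol=1e-12, max_iter=500).fit(X)
        assert log_likelihood(X, model) == pytest.approx(
            ref.score(X) * len(X), abs=1e-6)
        order = np.argsort(model.means[:, 0])
        ref_order = np.argsort(ref.means_[:, 0])
        assert np.allclose(model.means[order], ref.means_[ref_order], atol=1e-4)


class TestEstimatorAndSerialization:
    def test_sklearn_estimator_contract(self, rng):
        X, y = two_blob_data(rng, n=100)
        est = GaussianMixtureEM(n_components=2, random_state=0)
        assert est.get_params()["n_components"] == 2
        est.set_params(tol=1e-8).fit(X)
        assert est.labels_.shape == (100,)
        assert est.predict(X[:5]).shape == (5,)
        assert np.allclose(est.predict_proba(X[:5]).sum(axis=1), 1.0)
        assert est.score(X) == pytest.approx(est.score_total(X) / 100)

    def test_json_round_trip_exact(self, rng):
        X, _ = two_blob_data(rng, n=60)
        est = GaussianMixtureEM(n_components=2, random_state=1).fit(X)
        doc = model_to_dict(est.model_, trace=est.trace_, seed=1)
        back = model_from_dict(doc)
        assert np.array_equal(back.weights, est.model_.weights)
        assert np.array_equal(back.means, est.model_.means)
        assert np.array_equal(back.covariances, est.model_.covariances)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            GMMModel(np.array([0.6, 0.6]), np.zeros((2, 1)), np.ones((2, 1, 1)))
        with pytest.raises(ValueError):
            GMMModel(np.array([1.0]), np.zeros((1, 2)),
                     np.array([[[1.0, 0.5], [0.1, 1.0]]]))
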