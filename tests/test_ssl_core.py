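"""Graph construction and the closed-form hybrid solver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from sklearn.kernel_ridge import KernelRidge

from conftest import make_samples
from mlpi.features import Sample
from mlpi.ssl_core import (
    edge_weights,
    fit_mlpi,
    laplacian_quadratic,
    objective_value,
    predict,
    predict_density_map,
    predict_samples,
    rbf_gram,
)


def sample_at(z, pi, y=None, pid="p"):
    return Sample(z=tuple(z), pi=pi, patient_id=pid, location=(0, 0), y=y)


class TestEdgeWeights:
    def test_identical_samples_weight_one(self):
        s = sample_at((1.0, 2.0), 0.5)
        g = edge_weights([s, s], psi_z=1.0, psi_pi=1.0)
        assert g.W[0, 1] == pytest.approx(1.0)

    def test_hand_value_unit_distance(self):
        a, b = sample_at((0.0, 0.0), 0.3), sample_at((1.0, 0.0), 0.3)
        g = edge_weights([a, b], psi_z=1.0, psi_pi=1.0)
        assert g.W[0, 1] == pytest.approx(0.60653, abs=1e-5)

    def test_wide_pi_bandwidth_leaves_image_factor(self):
        a, b = sample_at((0.0, 0.0), 0.0), sample_at((1.0, 0.0), 1.0)
        g = edge_weights([a, b], psi_z=1.0, psi_pi=1e9)
        assert g.W[0, 1] == pytest.approx(np.exp(-0.5), rel=1e-6)

    def test_laplacian_structure(self, rng):
        samples = make_samples(rng, 6, labeled=False)
        g = edge_weights(samples)
        assert np.allclose(g.W, g.W.T)
        assert np.allclose(np.diag(g.W), 1.0)
        assert np.allclose(g.Omega.sum(axis=1), 0.0, atol=1e-12)
        eigvals = np.linalg.eigvalsh(g.Omega)
        assert eigvals.min() >= -1e-10

    def test_zero_bandwidth_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            edge_weights(make_samples(rng, 3, labeled=False), psi_z=0.0, psi_pi=1.0)


class TestLaplacianQuadratic:
    def test_constant_vector_is_null(self, rng):
        g = edge_weights(make_samples(rng, 5, labeled=False))
        assert laplacian_quadratic(g.Omega, np.full(5, 3.7)) == pytest.approx(0.0, abs=1e-10)

    @given(st.integers(min_value=0, max_value=1000))
    def test_matches_pairwise_sum(self, seed):
        """f^T Omega f equals the half-sum of weighted squared differences."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        W = rng.uniform(0, 1, (n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        Omega = np.diag(W.sum(axis=1)) - W
        f = rng.normal(size=n)
        brute = 0.5 * sum(
            W[i, j] * (f[i] - f[j]) ** 2 for i in range(n) for j in range(n)
        )
        assert laplacian_quadratic(Omega, f) == pytest.approx(brute, abs=1e-10)
        assert laplacian_quadratic(Omega, f) >= 0


class TestFitMlpi:
    def test_reduces_to_kernel_ridge_when_supervised(self, rng):
        """gamma_I = 0 with no unlabeled samples is exactly KRR."""
        labeled = make_samples(rng, 5, labeled=True)
        m = fit_mlpi(labeled, [], gamma_a=0.1, gamma_i=0.0, eta=1.0)
        X = np.array([s.x for s in labeled])
        y = np.array([s.y for s in labeled])
        kr = KernelRidge(alpha=0.1 * 5, kernel="rbf", gamma=1.0 / 2.0).fit(X, y)
        assert np.allclose(m.alpha, kr.dual_coef_, atol=1e-8)

    @pytest.mark.parametrize("trial", range(5))
    def test_closed_form_matches_numerical_minimizer(self, trial):
        """The central oracle: alpha from the linear system attains the
        objective minimum found by direct optimization over alpha."""
        rng = np.random.default_rng(trial)
        labeled = make_samples(rng, 6, labeled=True)
        unlabeled = make_samples(rng, 6, labeled=False)
        ga, gi, eta = 0.05, 0.3, 1.0
        graph = edge_weights(labeled + unlabeled)
        m = fit_mlpi(labeled, unlabeled, ga, gi, eta, graph)
        n = 12
        K = rbf_gram(m.X_train, m.X_train, eta)
        y = np.zeros(n)
        y[:6] = [s.y for s in labeled]
        j = np.zeros(n)
        j[:6] = 1.0
        obj = lambda a: objective_value(a, K, y, j, ga, gi, graph.Omega, graph.weight_sum)
        res = minimize(obj, np.zeros(n), method="L-BFGS-B",
                       options=dict(maxiter=5000, ftol=1e-16, gtol=1e-12))
        assert obj(m.alpha) <= res.fun * (1 + 1e-6) + 1e-12

    def test_heavy_ridge_shrinks_predictions_to_zero(self, rng):
        labeled = make_samples(rng, 5, labeled=True)
        m = fit_mlpi(labeled, [], gamma_a=1e8, gamma_i=0.0, eta=1.0)
        preds = predict_samples(m, labeled, clip=False)
        assert np.max(np.abs(preds)) <= 1e-4

    def test_stationarity_of_solution(self, rng):
        labeled = make_samples(rng, 5, labeled=True)
        unlabeled = make_samples(rng, 4, labeled=False)
        graph = edge_weights(labeled + unlabeled)
        m = fit_mlpi(labeled, unlabeled, 0.01, 0.1, 1.0, graph)
        K = rbf_gram(m.X_train, m.X_train, 1.0)
        n = 9
        y = np.zeros(n); y[:5] = [s.y for s in labeled]
        j = np.zeros(n); j[:5] = 1.0
        eps = 1e-6
        f0 = objective_value(m.alpha, K, y, j, 0.01, 0.1, graph.Omega, graph.weight_sum)
        grad = np.empty(n)
        for i in range(n):
            a = m.alpha.copy(); a[i] += eps
            grad[i] = (objective_value(a, K, y, j, 0.01, 0.1, graph.Omega, graph.weight_sum) - f0) / eps
        assert np.linalg.norm(grad) <= 1e-4 * max(1.0, abs(f0))

    def test_permutation_equivariance(self, rng):
        labeled = make_samples(rng, 6, labeled=True)
        m1 = fit_mlpi(labeled, [], 0.01, 0.0, 1.0)
        perm = [3, 1, 5, 0, 2, 4]
        m2 = fit_mlpi([labeled[i] for i in perm], [], 0.01, 0.0, 1.0)
        assert np.allclose(m2.alpha, m1.alpha[perm], atol=1e-9)
        x = rng.normal(size=(4, 3))
        assert np.allclose(predict(m1, x), predict(m2, x), atol=1e-9)

    def test_graph_penalty_monotone_in_gamma_i(self, rng):
        """Stronger graph regularization yields smoother fitted vectors."""
        labeled = make_samples(rng, 6, labeled=True)
        unlabeled = make_samples(rng, 6, labeled=False)
        graph = edge_weights(labeled + unlabeled)
        quads = []
        for gi in (0.0, 0.1, 1.0, 10.0, 100.0):
            m = fit_mlpi(labeled, unlabeled, 0.01, gi, 1.0, graph)
            K = rbf_gram(m.X_train, m.X_train, 1.0)
            quads.append(laplacian_quadratic(graph.Omega, K @ m.alpha))
        assert all(a >= b - 1e-10 for a, b in zip(quads, quads[1:]))

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="labeled"):
            fit_mlpi([], [], 0.1, 0.0, 1.0)
        with pytest.raises(ValueError, match="eta"):
            fit_mlpi(make_samples(rng, 3, True), [], 0.1, 0.0, 0.0)


class TestPredict:
    def test_two_term_hand_expansion(self):
        a = sample_at((0.0,), 0.0, y=1.0)
        b = sample_at((1.0,), 0.0, y=0.0)
        m = fit_mlpi([a, b], [], gamma_a=0.0, gamma_i=0.0, eta=1.0)
        x = np.array([[0.5, 0.0]])
        k1 = np.exp(-0.25 / 2.0)
        k2 = np.exp(-0.25 / 2.0)
        by_hand = m.alpha[0] * k1 + m.alpha[1] * k2
        assert predict(m, x, clip=False)[0] == pytest.approx(by_hand, abs=1e-12)

    def test_zero_coefficients_zero_prediction(self, rng):
        labeled = make_samples(rng, 3, labeled=True)
        m = fit_mlpi(labeled, [], 0.1, 0.0, 1.0)
        object.__setattr__(m, "alpha", np.zeros(3))
        assert np.all(predict(m, rng.normal(size=(5, 3))) == 0.0)

    def test_dimension_mismatch_rejected(self, rng):
        m = fit_mlpi(make_samples(rng, 3, labeled=True), [], 0.1, 0.0, 1.0)
        with pytest.raises(ValueError, match="dimension"):
            predict(m, np.zeros((2, 5)))


class TestDensityMap:
    def test_single_voxel_roi(self, rng):
        chans = [rng.normal(size=(32, 32))]
        pi = rng.uniform(size=(32, 32))
        labeled = [sample_at((0.1,), 0.5, y=0.6)] * 2
        m = fit_mlpi(labeled, [], 0.1, 0.0, 1.0)
        roi = np.zeros((32, 32), dtype=bool)
        roi[16, 16] = True
        field = predict_density_map(m, chans, pi, roi)
        assert np.count_nonzero(field.values) <= 1
        assert field.values[16, 16] >= 0.0

    def test_map_values_in_unit_interval(self, rng):
        chans = [rng.normal(size=(32, 32))]
        pi = rng.uniform(size=(32, 32))
        labeled = make_samples(rng, 5, labeled=True, n_channels=1)
        m = fit_mlpi(labeled, [], 1e-6, 0.0, 0.5)
        roi = np.zeros((32, 32), dtype=bool)
        roi[10:22, 10:22] = True
        field = predict_density_map(m, chans, pi, roi)
        assert field.values.min() >= 0.0 and field.values.max() <= 1.0

    def test_empty_roi_rejected(self, rng):
        m = fit_mlpi(make_samples(rng, 3, labeled=True, n_channels=1), [], 0.1, 0.0, 1.0)
        with pytest.raises(ValueError, match="empty"):
            predict_density_map(m, [np.zeros((8, 8))], np.zeros((8, 8)),
                                np.zeros((8, 8), dtype=bool))

    @pytest.mark.parametrize("seed", [5, 6])
    def test_graph_coupling_pulls_map_toward_pi(self, seed):
        """When image channels are weakly informative, turning on the graph
        penalty makes the transductive map (unlabeled = every ROI voxel)
        track the PI map's shape more closely than the supervised map."""
        from mlpi.features import build_labeled_samples, build_unlabeled_samples, standardize_channels
        from mlpi.synthetic import generate_phantom

        case = generate_phantom(seed=seed, blend_weight=0.5, n_biopsies=5, noise_sd=1.5)
        chans = standardize_channels(case.channels, case.tissue.brain_mask)
        labeled = build_labeled_samples(chans, case.pi_field, case.biopsies)
        unlabeled = build_unlabeled_samples(chans, case.pi_field, case.roi_mask, "p", stride=1)

        m_pi = fit_mlpi(labeled, unlabeled, 1e-2, 1.0, 1.0)
        m_ml = fit_mlpi(labeled, [], 1e-2, 0.0, 1.0)
        roi = case.roi_mask
        f_pi = predict_density_map(m_pi, chans, case.pi_field, roi)
        f_ml = predict_density_map(m_ml, chans, case.pi_field, roi)
        ref = case.pi_field.values[roi]
        c_pi = np.corrcoef(f_pi.values[roi], ref)[0, 1]
        c_ml = np.corrcoef(f_ml.values[roi], ref)[0, 1]
        assert c_pi > c_ml
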