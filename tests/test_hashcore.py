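"""The hashing objective, its derivatives, and the block-Newton solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_toy_instance
from fedsimhash.errors import ConfigurationError, DimensionError
from fedsimhash.features import FeatureDomainSpec, SiteDataset, concatenate_sites
from fedsimhash.hashcore import (
    HashConfig,
    HashModel,
    SiteAux,
    derivatives_Q,
    derivatives_W,
    encode,
    fit_hash_model,
    objective_value,
    site_objective,
    surrogate_sign,
)


def fd_gradient_W(model, aux, site, cfg, eps=1e-6):
    W0 = model.W["l"].copy()
    g = np.zeros_like(W0)
    for idx in np.ndindex(W0.shape):
        for delta, sign in ((eps, 1.0), (-eps, -1.0)):
            model.W["l"] = W0.copy()
            model.W["l"][idx] += delta
            g[idx] += sign * site_objective(model, aux, site, cfg)
    model.W["l"] = W0
    return g / (2 * eps)


def fd_gradient_Q(model, aux, site, cfg, eps=1e-6):
    Q0 = aux.Q["l"].copy()
    g = np.zeros_like(Q0)
    for idx in np.ndindex(Q0.shape):
        for delta, sign in ((eps, 1.0), (-eps, -1.0)):
            aux.Q["l"] = Q0.copy()
            aux.Q["l"][idx] += delta
            g[idx] += sign * site_objective(model, aux, site, cfg)
    aux.Q["l"] = Q0
    return g / (2 * eps)


class TestSurrogateSign:
    def test_scalar_formula(self):
        assert surrogate_sign(np.array(3.0), 16.0) == pytest.approx(0.6)

    def test_zero_maps_to_zero(self):
        assert surrogate_sign(np.array(0.0), 0.5) == 0.0

    def test_sharpens_toward_sign_as_xi_shrinks(self):
        vals = [float(surrogate_sign(np.array(1.0), xi)) for xi in (1.0, 0.1, 1e-4)]
        assert vals == sorted(vals) and vals[-1] > 0.99

    def test_nonpositive_xi_rejected(self):
        with pytest.raises(ConfigurationError):
            surrogate_sign(np.zeros(2), 0.0)

    @given(st.floats(-50, 50), st.floats(1e-3, 10))
    @settings(max_examples=50, deadline=None)
    def test_bounded_odd_and_sign_preserving(self, q, xi):
        s = float(surrogate_sign(np.array(q), xi))
        assert -1 < s < 1
        assert np.sign(s) == np.sign(q)
        assert float(surrogate_sign(np.array(-q), xi)) == pytest.approx(-s)


class TestObjective:
    def test_all_zero_is_zero(self):
        model, aux, site, cfg = make_toy_instance(0)
        model.W["l"][:] = 0
        aux.Q["l"][:] = 0
        assert objective_value(model, [aux], [site], cfg) == 0.0

    def test_matches_scalar_hand_expansion(self):
        """n=2, d=1, b=1 instance expanded with scalar arithmetic."""
        spec = FeatureDomainSpec((("l", ("l_0",)),))
        p1, p2, w, q1, q2 = 0.7, -1.3, 0.4, 0.9, -0.2
        lam, eta, xi = 0.5, 1e-3, 0.5
        site = SiteDataset(0, spec, {"l": np.array([[p1, p2]])}, np.array([1, 0]))
        model = HashModel(spec, {"l": np.array([[w]])})
        aux = SiteAux(0, {"l": np.array([[q1, q2]])})
        cfg = HashConfig(bits_per_domain=(1,), lambda_sup=lam, eta=eta, xi=xi)
        s1 = q1 / np.sqrt(q1**2 + xi)
        s2 = q2 / np.sqrt(q2**2 + xi)
        # R = [[0,-1],[-1,0]] (different labels): tr(-S R S^T) = 2 s1 s2
        expected = (
            (w * p1 - s1) ** 2
            + (w * p2 - s2) ** 2
            + lam * 2 * s1 * s2
            + eta * (q1**2 + q2**2)
        )
        assert objective_value(model, [aux], [site], cfg) == pytest.approx(expected, rel=1e-12)

    def test_additive_over_sites(self):
        model, aux1, site1, cfg = make_toy_instance(1)
        _, aux2, site2, _ = make_toy_instance(2)
        total = objective_value(model, [aux1, aux2], [site1, site2], cfg)
        parts = site_objective(model, aux1, site1, cfg) + site_objective(model, aux2, site2, cfg)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_shape_mismatch_names_domain(self):
        model, aux, site, cfg = make_toy_instance(0)
        aux.Q["l"] = aux.Q["l"][:, :2]
        with pytest.raises(DimensionError, match="'l'"):
            objective_value(model, [aux], [site], cfg)


class TestDerivatives:
    @pytest.mark.parametrize("seed", range(6))
    def test_W_gradient_matches_finite_differences(self, seed):
        model, aux, site, cfg = make_toy_instance(seed)
        grad, hess = derivatives_W("l", model, aux, site, cfg)
        fd = fd_gradient_W(model, aux, site, cfg)
        assert np.abs(fd - grad).max() <= 1e-5 * max(1.0, np.abs(grad).max())
        np.testing.assert_allclose(hess, hess.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(hess)) >= -1e-10  # PSD up to roundoff

    @pytest.mark.parametrize("seed", range(6))
    def test_Q_gradient_matches_finite_differences(self, seed):
        model, aux, site, cfg = make_toy_instance(seed)
        grad, hess = derivatives_Q(0, "l", model, aux, site, cfg)
        fd = fd_gradient_Q(model, aux, site, cfg)
        assert np.abs(fd - grad).max() <= 1e-5 * max(1.0, np.abs(grad).max())
        np.testing.assert_allclose(hess, hess.T, atol=1e-12)

    def test_Q_hessian_matches_fd_of_gradient(self):
        model, aux, site, cfg = make_toy_instance(4)
        _, hess = derivatives_Q(0, "l", model, aux, site, cfg)
        Q0 = aux.Q["l"].copy()
        eps = 1e-6
        m = Q0.size
        fd = np.zeros((m, m))
        for j in range(m):
            for delta, sign in ((eps, 1.0), (-eps, -1.0)):
                flat = Q0.copy().reshape(-1)
                flat[j] += delta
                aux.Q["l"] = flat.reshape(Q0.shape)
                g, _ = derivatives_Q(0, "l", model, aux, site, cfg)
                fd[:, j] += sign * g.reshape(-1)
        fd /= 2 * eps
        aux.Q["l"] = Q0
        assert np.abs(fd - hess).max() <= 1e-5 * np.abs(hess).max()

    def test_W_gradient_vanishes_at_least_squares_solution(self):
        model, aux, site, cfg = make_toy_instance(3)
        cfg = HashConfig(bits_per_domain=(2,), lambda_sup=0.0, eta=cfg.eta, xi=cfg.xi)
        P = site.P["l"]
        S = surrogate_sign(aux.Q["l"], cfg.xi)
        model.W["l"] = np.linalg.solve(P @ P.T, P @ S.T)  # normal equations
        grad, _ = derivatives_W("l", model, aux, site, cfg)
        assert np.abs(grad).max() < 1e-10

    def test_Q_supervised_portion_linear_in_lambda(self):
        model, aux, site, _ = make_toy_instance(5)

        def grad_at(lam):
            cfg = HashConfig(bits_per_domain=(2,), lambda_sup=lam, eta=1e-3, xi=0.5)
            return derivatives_Q(0, "l", model, aux, site, cfg)[0]

        g0, g1, g2 = grad_at(0.0), grad_at(0.7), grad_at(1.4)
        np.testing.assert_allclose(g2 - g0, 2 * (g1 - g0), rtol=1e-10)

    def test_empty_site_has_zero_derivatives(self):
        model, aux, site, cfg = make_toy_instance(0)
        empty = site.subset(np.array([], dtype=int))
        aux_empty = SiteAux(0, {"l": np.zeros((2, 0))})
        grad, hess = derivatives_W("l", model, aux_empty, empty, cfg)
        assert np.all(grad == 0) and np.all(hess == 0)


class TestFit:
    def test_infinite_rel_tol_returns_initialization(self, two_sites):
        cfg = HashConfig(seed=4, rel_tol=float("inf"))
        model, aux, trace = fit_hash_model(two_sites, cfg)
        assert len(trace) == 1
        from fedsimhash.hashcore import init_model

        init = init_model(two_sites[0].spec, cfg)
        for tag in model.spec.tags:
            np.testing.assert_array_equal(model.W[tag], init.W[tag])

    def test_trace_non_increasing_and_strictly_decreased(self, two_sites):
        cfg = HashConfig(seed=4, max_iter=6)
        _, _, trace = fit_hash_model(two_sites, cfg)
        assert all(a >= b for a, b in zip(trace, trace[1:]))
        assert trace[-1] < trace[0]

    def test_seed_determinism(self, two_sites):
        cfg = HashConfig(seed=4, max_iter=3)
        m1, _, t1 = fit_hash_model(two_sites, cfg)
        m2, _, t2 = fit_hash_model(two_sites, cfg)
        assert t1 == t2
        for tag in m1.spec.tags:
            np.testing.assert_array_equal(m1.W[tag], m2.W[tag])

    def test_concatenated_equals_per_site_trace(self, two_sites):
        cfg = HashConfig(seed=5, max_iter=8)
        _, _, tr_split = fit_hash_model(two_sites, cfg)
        _, _, tr_pool = fit_hash_model([concatenate_sites(two_sites)], cfg)
        assert len(tr_split) == len(tr_pool)
        np.testing.assert_allclose(tr_split, tr_pool, rtol=1e-8)

    @pytest.mark.parametrize("xi", [0.5, 1e-2])
    def test_monotone_across_xi(self, two_sites, xi):
        cfg = HashConfig(seed=2, max_iter=4, xi=xi)
        _, _, trace = fit_hash_model(two_sites, cfg)
        assert all(a >= b for a, b in zip(trace, trace[1:]))


class TestEncode:
    def test_sign_of_projection_with_tie_convention(self):
        spec = FeatureDomainSpec((("l", ("l_0", "l_1")),))
        model = HashModel(spec, {"l": np.array([[1.0], [-1.0]])})
        P = {"l": np.array([[1.0, 0.0, 0.3], [1.0, 0.0, 0.9]])}
        H = encode(model, P).codes["l"]
        # projections: 0.0, 0.0, -0.6 -> sign(0) = +1
        assert H.tolist() == [[1, 1, -1]]

    def test_negating_W_negates_nonzero_codes(self, two_sites):
        cfg = HashConfig(seed=1, max_iter=2)
        model, _, _ = fit_hash_model(two_sites, cfg)
        H1 = encode(model, two_sites[0].P).codes
        for tag in model.spec.tags:
            model.W[tag] = -model.W[tag]
        H2 = encode(model, two_sites[0].P).codes
        for tag in H1:
            proj_nonzero = H1[tag] * H2[tag] == -1
            assert np.mean(proj_nonzero) > 0.95  # ties (exact zeros) are rare

    def test_matches_bruteforce_sign(self, two_sites):
        cfg = HashConfig(seed=1, max_iter=2)
        model, _, _ = fit_hash_model(two_sites, cfg)
        H = encode(model, two_sites[1].P).codes
        for tag in model.spec.tags:
            proj = model.W[tag].T @ two_sites[1].P[tag]
            brute = np.array(
                [[1 if proj[a, j] >= 0 else -1 for j in range(proj.shape[1])]
                 for a in range(proj.shape[0])]
            )
            np.testing.assert_array_equal(H[tag], brute)

    def test_sign_of_surrogate_matches_sign_of_q(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=(4, 7))
        S = surrogate_sign(Q, 0.3)
        np.testing.assert_array_equal(np.sign(S[Q != 0]), np.sign(Q[Q != 0]))

    def test_dimension_mismatch_rejected(self):
        spec = FeatureDomainSpec((("l", ("l_0", "l_1")),))
        model = HashModel(spec, {"l": np.zeros((2, 3))})
        with pytest.raises(DimensionError):
            encode(model, {"l": np.zeros((5, 4))})
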