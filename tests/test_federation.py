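"""Message-boundary federation: aggregate-only exchange, centralized equivalence."""

import numpy as np
import pytest

from fedsimhash.errors import ProtocolError
from fedsimhash.features import concatenate_sites
from fedsimhash.federation import (
    DerivativeBundle,
    FederationConfig,
    SiteNode,
    aggregate_and_update_W,
    federated_fit,
    local_W_statistics,
    validate_bundle,
)
from fedsimhash.hashcore import (
    HashConfig,
    derivatives_W,
    fit_hash_model,
    init_aux,
    init_model,
    newton_step_W,
)


@pytest.fixture()
def broadcast(two_sites):
    cfg = HashConfig(seed=6)
    model = init_model(two_sites[0].spec, cfg)
    auxes = [init_aux(model, s) for s in two_sites]
    return model, auxes, cfg


class TestBundles:
    def test_single_site_bundle_equals_centralized_derivative(self, two_sites, broadcast):
        model, auxes, cfg = broadcast
        tag = "l"
        bundle = local_W_statistics(two_sites[0], model, auxes[0], tag, cfg)
        grad, _ = derivatives_W(tag, model, auxes[0], two_sites[0], cfg)
        np.testing.assert_allclose(bundle.gradient, grad, rtol=1e-12)

    def test_bundles_sum_to_pooled_derivative(self, two_sites, broadcast):
        model, auxes, cfg = broadcast
        tag = "d"
        pooled = concatenate_sites(two_sites)
        aux_pooled = init_aux(model, pooled)
        grad_pooled, _ = derivatives_W(tag, model, aux_pooled, pooled, cfg)
        total = sum(
            local_W_statistics(s, model, a, tag, cfg).gradient
            for s, a in zip(two_sites, auxes)
        )
        assert np.abs(total - grad_pooled).max() <= 1e-10 * max(1.0, np.abs(grad_pooled).max())

    def test_schema_rejects_patient_axis_payload(self, two_sites, broadcast):
        model, auxes, cfg = broadcast
        bundle = local_W_statistics(two_sites[0], model, auxes[0], "l", cfg)
        d_k, b_k = model.W["l"].shape
        n = two_sites[0].n_patients
        bad = DerivativeBundle(
            site=0, k="l",
            gradient=np.zeros((b_k, n)),  # smuggled patient-level (Q-shaped) matrix
            hessian=bundle.hessian, cross=bundle.cross,
            n_patients=n, snorm=bundle.snorm, model_version=0,
        )
        with pytest.raises(ProtocolError, match="gradient"):
            validate_bundle(bad, d_k, model.W["l"].shape[1], n)

    def test_valid_bundle_passes_schema(self, two_sites, broadcast):
        model, auxes, cfg = broadcast
        bundle = local_W_statistics(two_sites[0], model, auxes[0], "l", cfg)
        validate_bundle(bundle, model.W["l"].shape[0], model.W["l"].shape[1],
                        two_sites[0].n_patients)

    def test_stale_model_version_is_protocol_error(self, two_sites, broadcast):
        model, auxes, cfg = broadcast
        node = SiteNode(two_sites[0], cfg)
        node.receive_model(model, version=0)
        with pytest.raises(ProtocolError, match="stale"):
            node.w_bundle("l", version=3)


class TestAggregation:
    def test_zero_gradient_leaves_W_unchanged(self, two_sites, broadcast):
        model, auxes, cfg = broadcast
        tag = "l"
        W = model.W[tag]
        G2 = np.eye(W.shape[0])
        C = G2 @ W  # gradient 2(G2 W - C) = 0
        bundle = DerivativeBundle(
            site=0, k=tag, gradient=np.zeros_like(W), hessian=2 * G2, cross=C,
            n_patients=1, snorm=0.0, model_version=0,
        )
        W_new = aggregate_and_update_W([bundle], model, tag, cfg)
        np.testing.assert_allclose(W_new, W, atol=1e-12)

    def test_federated_round_equals_centralized_block_update(self, two_sites, broadcast):
        model, auxes, cfg = broadcast
        tag = "p"
        bundles = [
            local_W_statistics(s, model, a, tag, cfg) for s, a in zip(two_sites, auxes)
        ]
        W_fed = aggregate_and_update_W(bundles, model, tag, cfg)
        from fedsimhash.hashcore import aggregate_w_stats, w_statistics

        stats = [w_statistics(s, a, tag, cfg) for s, a in zip(two_sites, auxes)]
        G2, C, _ = aggregate_w_stats(stats)
        W_cent = newton_step_W(model.W[tag], G2, C, cfg)
        np.testing.assert_allclose(W_fed, W_cent, rtol=1e-8)

    def test_three_replicas_equal_tripled_single_site(self, two_sites, broadcast):
        """Newton direction is invariant to replicating a site three times."""
        model, auxes, cfg = broadcast
        tag = "c"
        b = local_W_statistics(two_sites[0], model, auxes[0], tag, cfg)
        W_rep = aggregate_and_update_W([b, b, b], model, tag, cfg)
        tripled = DerivativeBundle(
            site=0, k=tag, gradient=3 * b.gradient, hessian=3 * b.hessian,
            cross=3 * b.cross, n_patients=3 * b.n_patients, snorm=3 * b.snorm,
            model_version=0,
        )
        W_single = aggregate_and_update_W([tripled], model, tag, cfg)
        np.testing.assert_allclose(W_rep, W_single, rtol=1e-10)

    def test_mismatched_bundles_rejected(self, two_sites, broadcast):
        model, auxes, cfg = broadcast
        b1 = local_W_statistics(two_sites[0], model, auxes[0], "l", cfg, version=0)
        b2 = local_W_statistics(two_sites[1], model, auxes[1], "l", cfg, version=1)
        with pytest.raises(ProtocolError):
            aggregate_and_update_W([b1, b2], model, "l", cfg)


class TestFederatedFit:
    def test_single_site_bit_identical_to_centralized(self, two_sites):
        cfg = HashConfig(seed=9, max_iter=4)
        m_fed, _, tr_fed = federated_fit([two_sites[0]], cfg, FederationConfig(M=1))
        m_cen, _, tr_cen = fit_hash_model([two_sites[0]], cfg)
        assert tr_fed == tr_cen
        for tag in m_fed.spec.tags:
            np.testing.assert_array_equal(m_fed.W[tag], m_cen.W[tag])

    def test_multi_site_trace_matches_centralized(self, two_sites):
        cfg = HashConfig(seed=9, max_iter=6)
        _, _, tr_fed = federated_fit(two_sites, cfg, FederationConfig(M=2))
        _, _, tr_cen = fit_hash_model(two_sites, cfg)
        np.testing.assert_allclose(tr_fed, tr_cen, rtol=1e-6)

    def test_message_log_carries_only_aggregate_shapes(self, two_sites):
        """Structural audit: every exchanged payload is a d_k x b_k or
        d_k x d_k aggregate (or a scalar); never P/Q/H/R-shaped."""
        cfg = HashConfig(seed=9, max_iter=2)
        log = []
        _, nodes, _ = federated_fit(two_sites, cfg, FederationConfig(M=2), message_log=log)
        assert log, "audit log should not be empty"
        spec = two_sites[0].spec
        bits = dict(zip(spec.tags, cfg.bits_for(spec)))
        dims = dict(zip(spec.tags, spec.dims))
        allowed = {(dims[t], bits[t]) for t in spec.tags} | {(dims[t], dims[t]) for t in spec.tags}
        for msg in log:
            pd = msg.get("payload_dims")
            shapes = []
            if isinstance(pd, dict):
                shapes = [tuple(v) for v in pd.values() if isinstance(v, list)]
            elif isinstance(pd, list):
                shapes = [tuple(pd)]
            for shape in shapes:
                assert shape in allowed, f"non-aggregate payload in {msg}"

    def test_q_and_codes_stay_on_site(self, two_sites):
        cfg = HashConfig(seed=9, max_iter=2)
        log = []
        model, nodes, _ = federated_fit(two_sites, cfg, FederationConfig(M=2), message_log=log)
        types = {m["type"] for m in log}
        assert types <= {"model", "bundle", "objective", "ack"}
        for node in nodes:
            codes = node.local_codes()
            assert set(np.unique(codes.concatenated(model.spec.tags))) <= {-1, 1}

    def test_site_count_mismatch_is_protocol_error(self, two_sites):
        with pytest.raises(ProtocolError):
            federated_fit(two_sites, HashConfig(seed=0), FederationConfig(M=3))

    def test_asynchronous_schedule_is_stub(self):
        with pytest.raises(NotImplementedError):
            FederationConfig(M=2, schedule="asynchronous")
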