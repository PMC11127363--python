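"""Flow layers and density: closed forms, Jacobian oracles, invertibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import numerical_jacobian, randomize_flow
from phrflow.flow.core import ConditionalFlow, FlowConfig, anomaly_score
from phrflow.flow.layers import ConditionalAffine, GinBlock, GinCoupling

LOG_2PI = np.log(2 * np.pi)


class TestConditionalAffine:
    def test_zero_network_is_identity(self, rng):
        layer = ConditionalAffine(d=4, d_c=2, hidden=8, alpha=1.9, rng=rng)
        x = rng.normal(size=(3, 4))
        c = rng.normal(size=(3, 2))
        u, logdet, _ = layer.forward(x, c)
        assert np.allclose(u, x)
        assert np.allclose(logdet, 0.0)

    def test_closed_form_scalar_case(self, rng):
        # force a' = ln 2, b = 1 by setting the output bias directly
        layer = ConditionalAffine(d=1, d_c=1, hidden=4, alpha=3.0, rng=rng)
        target_a = np.arctanh(np.log(2.0) / 3.0)
        layer.net.params["b2"][...] = [target_a, 1.0]
        u, logdet, _ = layer.forward(np.array([[3.0]]), np.array([[0.0]]))
        assert u[0, 0] == pytest.approx(7.0, abs=1e-12)
        assert logdet[0] == pytest.approx(np.log(2.0), abs=1e-12)

    def test_logdet_matches_numerical_jacobian(self, rng):
        layer = ConditionalAffine(d=4, d_c=2, hidden=8, alpha=1.9, rng=rng)
        for p in layer.net.params.values():
            p[...] = rng.normal(0, 0.5, p.shape)
        x = rng.normal(size=4)
        c = rng.normal(size=(1, 2))
        _, logdet, _ = layer.forward(x[None], c)
        J = numerical_jacobian(lambda v: layer.forward(v[None], c)[0][0], x)
        assert logdet[0] == pytest.approx(
            np.log(abs(np.linalg.det(J))), abs=1e-4
        )

    def test_inverse_recovers_input(self, rng):
        layer = ConditionalAffine(d=5, d_c=2, hidden=8, alpha=1.9, rng=rng)
        for p in layer.net.params.values():
            p[...] = rng.normal(0, 0.5, p.shape)
        x = rng.normal(size=(10, 5))
        c = rng.normal(size=(10, 2))
        u, _, _ = layer.forward(x, c)
        assert np.allclose(layer.inverse(u, c), x, atol=1e-10)


class TestGinCoupling:
    def test_zero_subnets_identity(self, rng):
        layer = GinCoupling(d=6, d_c=2, hidden=8, active_first=True, rng=rng)
        x = rng.normal(size=(4, 6))
        c = rng.normal(size=(4, 2))
        u, _ = layer.forward(x, c)
        assert np.allclose(u, x)

    def test_passive_half_bit_exact(self, rng):
        layer = GinCoupling(d=7, d_c=2, hidden=8, active_first=True, rng=rng)
        for sub in (layer.s_net, layer.t_net):
            for p in sub.params.values():
                p[...] = rng.normal(0, 0.5, p.shape)
        x = rng.normal(size=(5, 7))
        c = rng.normal(size=(5, 2))
        u, _ = layer.forward(x, c)
        assert np.array_equal(u[:, layer.passive], x[:, layer.passive])

    def test_unit_jacobian_determinant(self, rng):
        layer = GinCoupling(d=6, d_c=2, hidden=8, active_first=False, rng=rng)
        for sub in (layer.s_net, layer.t_net):
            for p in sub.params.values():
                p[...] = rng.normal(0, 0.5, p.shape)
        x = rng.normal(size=6)
        c = rng.normal(size=(1, 2))
        J = numerical_jacobian(lambda v: layer.forward(v[None], c)[0][0], x)
        assert abs(np.linalg.det(J)) == pytest.approx(1.0, abs=1e-6)

    def test_zero_sum_log_scales(self, rng):
        layer = GinCoupling(d=8, d_c=2, hidden=8, active_first=True, rng=rng)
        for p in layer.s_net.params.values():
            p[...] = rng.normal(0, 1.0, p.shape)
        x = rng.normal(size=(3, 8))
        c = rng.normal(size=(3, 2))
        _, _, rc, _, _, _ = layer._scales(x[:, layer.passive], c)
        assert np.allclose(rc.sum(axis=1), 0.0, atol=1e-12)


class TestGinBlock:
    def test_identity_configuration(self, rng):
        block = GinBlock(d=6, d_c=2, hidden=8, rng=rng)
        block.perm = np.arange(6)
        block.inv_perm = np.arange(6)
        x = rng.normal(size=(4, 6))
        c = rng.normal(size=(4, 2))
        u, _ = block.forward(x, c)
        assert np.allclose(u, x)

    def test_permutation_and_offset_only(self, rng):
        block = GinBlock(d=5, d_c=2, hidden=8, rng=rng)
        v = rng.normal(size=5)
        block.params["t_global"][...] = v
        x = rng.normal(size=(3, 5))
        c = rng.normal(size=(3, 2))
        u, _ = block.forward(x, c)
        assert np.allclose(u, x[:, block.perm] + v)
        assert np.allclose(block.inverse(u, c), x, atol=1e-12)

    def test_roundtrip_high_dimension(self, rng):
        block = GinBlock(d=48, d_c=2, hidden=32, rng=rng)
        for _, p, _ in block.named_parameters():
            p[...] = rng.normal(0, 0.3, p.shape)
        x = rng.normal(size=(20, 48))
        c = rng.normal(size=(20, 2))
        u, _ = block.forward(x, c)
        assert np.abs(block.inverse(u, c) - x).max() < 1e-5


class TestFullFlow:
    def test_fresh_flow_is_permuted_identity_with_zero_logdet(self, rng):
        flow = ConditionalFlow(FlowConfig(d=6, d_c=2, n_blocks=2,
                                          hidden_width=8, seed=0))
        x = rng.normal(size=(5, 6))
        c = rng.normal(size=(5, 2))
        z, logdet = flow.forward(x, c)
        assert np.allclose(logdet, 0.0)
        perm = np.arange(6)
        for blk in flow.blocks:
            perm = perm[blk.perm]
        assert np.allclose(z, x[:, perm])

    def test_forward_inverse_roundtrip(self, small_flow, rng):
        for _ in range(20):
            x = rng.normal(size=(5, 6))
            c = rng.normal(size=(5, 2))
            z, _ = small_flow.forward(x, c)
            assert np.abs(small_flow.inverse(z, c) - x).max() < 1e-5

    def test_total_logdet_matches_numerical_jacobian(self, small_flow, rng):
        x = rng.normal(size=6)
        c = rng.normal(size=(1, 2))
        _, logdet = small_flow.forward(x[None], c)
        J = numerical_jacobian(lambda v: small_flow.forward(v[None], c)[0][0], x)
        assert logdet[0] == pytest.approx(
            np.log(abs(np.linalg.det(J))), abs=1e-3
        )

    def test_condition_changes_the_map(self, small_flow, rng):
        x = rng.normal(size=(1, 6))
        z1, _ = small_flow.forward(x, np.array([[0.0, 0.0]]))
        z2, _ = small_flow.forward(x, np.array([[2.0, 1.0]]))
        assert np.abs(z1 - z2).max() > 1e-3

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bijectivity_across_random_configs(self, seed):
        r = np.random.default_rng(seed)
        d = int(r.integers(2, 12))
        cfg = FlowConfig(d=d, d_c=2, n_blocks=int(r.integers(1, 4)),
                         hidden_width=8, seed=seed)
        flow = randomize_flow(ConditionalFlow(cfg), r, scale=0.4)
        x = r.normal(size=(6, d))
        c = r.normal(size=(6, 2))
        z, _ = flow.forward(x, c)
        assert np.abs(flow.inverse(z, c) - x).max() < 1e-5

    def test_nonfinite_input_rejected(self, small_flow):
        x = np.full((1, 6), np.nan)
        with pytest.raises(Exception):
            small_flow.forward(x, np.zeros((1, 2)))

    def test_save_load_roundtrip(self, small_flow, tmp_path, rng):
        path = tmp_path / "flow.npz"
        small_flow.save(path)
        loaded = ConditionalFlow.load(path)
        x = rng.normal(size=(4, 6))
        c = rng.normal(size=(4, 2))
        assert np.allclose(loaded.log_likelihood(x, c),
                           small_flow.log_likelihood(x, c))


class TestLogLikelihood:
    def _identity_flow(self, d):
        return ConditionalFlow(FlowConfig(d=d, d_c=2, n_blocks=1,
                                          hidden_width=4, seed=0))

    def test_standard_normal_origin_d2(self):
        flow = self._identity_flow(2)
        ll = flow.log_likelihood(np.zeros((1, 2)), np.zeros((1, 2)))
        assert ll[0] == pytest.approx(-LOG_2PI, abs=1e-12)

    def test_standard_normal_at_one_d2(self):
        # permutation-only flow: density at (1, 0) equals N(0,I) at (1, 0)
        flow = self._identity_flow(2)
        x = np.array([[1.0, 0.0]])
        ll = flow.log_likelihood(x, np.zeros((1, 2)))
        assert ll[0] == pytest.approx(-LOG_2PI - 0.5, abs=1e-12)

    def test_density_integrates_to_one_d2(self, rng):
        from conftest import density_integral_2d

        cfg = FlowConfig(d=2, d_c=2, n_blocks=2, hidden_width=8, seed=3)
        flow = randomize_flow(ConditionalFlow(cfg), rng, scale=0.3)
        integral = density_integral_2d(flow, np.array([0.5, 1.0]))
        assert integral == pytest.approx(1.0, rel=0.02)

    def test_mean_loglik_matches_pushforward_entropy(self, rng):
        # for fixed c the log-det is a constant, so the pushforward
        # differential entropy is H(base) - logdet in closed form
        cfg = FlowConfig(d=2, d_c=2, n_blocks=2, hidden_width=8, seed=4)
        flow = randomize_flow(ConditionalFlow(cfg), rng, scale=0.3)
        flow.base_params["mu"][...] = 0.0
        flow.base_params["log_sigma"][...] = 0.0
        c_row = np.array([[0.3, 1.0]])
        n = 20_000
        c = np.tile(c_row, (n, 1))
        x = flow.sample(c, rng)
        _, logdet = flow.forward(x[:1], c[:1])
        entropy = 2 * 0.5 * (1 + LOG_2PI) - logdet[0]
        mc = -flow.log_likelihood(x, c).mean()
        assert mc == pytest.approx(entropy, abs=0.02)


class TestAnomalyScore:
    def test_origin_is_global_minimum(self):
        assert anomaly_score(np.zeros((1, 3)))[0] == -1.0

    def test_closed_form_at_norm_sqrt2(self):
        z = np.array([[1.0, 1.0]])
        assert anomaly_score(z)[0] == pytest.approx(-np.exp(-1.0))

    def test_ordering_reverses_base_density(self, rng):
        z = rng.normal(size=(50, 4))
        scores = anomaly_score(z)
        density = np.exp(-0.5 * (z ** 2).sum(axis=1))
        assert np.array_equal(np.argsort(scores), np.argsort(-density))

    def test_range(self, rng):
        s = anomaly_score(rng.normal(size=(100, 6)) * 3)
        assert np.all(s >= -1.0) and np.all(s < 0.0)
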