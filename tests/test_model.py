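"""Architecture contracts: activation, attention, sharing, parameter budget."""

import dataclasses

import numpy as np
import pytest

from siamvitals import nn
from siamvitals.model import (
    MULTITASK_PARAM_BUDGET,
    SINGLE_TASK_PARAM_BUDGET,
    ModelSpec,
    build_model,
    count_parameters,
    leaky_relu,
)
from siamvitals.train import pearson_loss_grad

from conftest import tiny_model_spec


class TestLeakyRelu:
    @pytest.mark.parametrize("x, expected", [(5.0, 5.0), (-100.0, -1.0), (0.0, 0.0)])
    def test_scalar_values(self, x, expected):
        assert leaky_relu(x) == expected

    def test_array_and_custom_slope(self):
        out = leaky_relu(np.array([-2.0, 3.0]), alpha=0.1)
        assert np.allclose(out, [-0.2, 3.0])


def _loop_channel_gates(layer: nn.ChannelAttention, x: np.ndarray) -> np.ndarray:
    """Brute-force reimplementation with explicit loops."""
    B, H, W, C = x.shape
    gates = np.zeros((B, C))
    for b in range(B):
        out = np.zeros(C)
        for pooled in (x[b].mean(axis=(0, 1)), x[b].max(axis=(0, 1))):
            h = pooled @ layer.w1.value + layer.b1.value
            h = np.where(h >= 0, h, layer.alpha * h)
            out += h @ layer.w2.value + layer.b2.value
        gates[b] = 1.0 / (1.0 + np.exp(-out))
    return gates


def _loop_spatial_gates(layer: nn.SpatialAttention, x: np.ndarray) -> np.ndarray:
    B, H, W, C = x.shape
    k = layer.conv.kernel
    p = k // 2
    w = layer.conv.w.value  # (k, k, 2, 1)
    bias = layer.conv.b.value[0]
    gates = np.zeros((B, H, W))
    stacked = np.stack([x.mean(axis=3), x.max(axis=3)], axis=-1)
    for b in range(B):
        padded = np.pad(stacked[b], ((p, p), (p, p), (0, 0)))
        for i in range(H):
            for j in range(W):
                acc = bias
                for u in range(k):
                    for v in range(k):
                        for c in range(2):
                            acc += padded[i + u, j + v, c] * w[u, v, c, 0]
                gates[b, i, j] = 1.0 / (1.0 + np.exp(-acc))
    return gates


class TestChannelAttention:
    def test_zero_weights_give_half_gates(self):
        layer = nn.ChannelAttention(8, 2, np.random.default_rng(0))
        for p in layer.params():
            p.value[...] = 0.0
        x = np.random.default_rng(1).normal(size=(3, 5, 5, 8))
        assert np.allclose(layer.gates(x), 0.5)

    def test_spatial_permutation_invariance(self):
        layer = nn.ChannelAttention(8, 2, np.random.default_rng(0))
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 6, 6, 8))
        perm = rng.permutation(36)
        xp = x.reshape(2, 36, 8)[:, perm, :].reshape(2, 6, 6, 8)
        assert np.allclose(layer.gates(x), layer.gates(xp))

    def test_matches_loop_oracle(self):
        layer = nn.ChannelAttention(8, 4, np.random.default_rng(3))
        x = np.random.default_rng(4).normal(size=(4, 6, 6, 8))
        assert np.allclose(layer.gates(x), _loop_channel_gates(layer, x), atol=1e-12)

    def test_gates_strictly_inside_unit_interval(self):
        layer = nn.ChannelAttention(8, 8, np.random.default_rng(5))
        x = np.random.default_rng(6).normal(size=(2, 6, 6, 8)) * 100
        g = layer.gates(x)
        assert np.all(g > 0) and np.all(g < 1)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            nn.ChannelAttention(8, 0, np.random.default_rng(0))


class TestSpatialAttention:
    def test_zero_weights_give_half_gates(self):
        layer = nn.SpatialAttention(7, np.random.default_rng(0))
        for p in layer.params():
            p.value[...] = 0.0
        x = np.random.default_rng(1).normal(size=(2, 6, 6, 8))
        assert np.allclose(layer.gates(x), 0.5)

    def test_channel_constant_input_collapses_mean_and_max(self):
        # with all channels equal, the mean and max maps coincide
        x = np.repeat(np.random.default_rng(2).normal(size=(1, 6, 6, 1)), 8, axis=3)
        assert np.allclose(x.mean(axis=3), x.max(axis=3))

    def test_matches_loop_oracle(self):
        layer = nn.SpatialAttention(7, np.random.default_rng(3))
        x = np.random.default_rng(4).normal(size=(2, 6, 6, 8))
        assert np.allclose(layer.gates(x), _loop_spatial_gates(layer, x), atol=1e-12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            nn.SpatialAttention(4, np.random.default_rng(0))


class TestBuildModel:
    def test_multitask_has_two_outputs(self):
        net = build_model(tiny_model_spec(multitask=True))
        x = np.random.default_rng(0).random((5, 6, 8, 3))
        pred = net.forward(x, x + 0.01)
        assert pred.ppg.shape == (5,)
        assert pred.respiration.shape == (5,)

    def test_single_task_has_one_output(self):
        net = build_model(tiny_model_spec(multitask=False))
        x = np.random.default_rng(0).random((5, 6, 8, 3))
        pred = net.forward(x, x)
        assert pred.respiration is None

    def test_swapping_inputs_preserves_ppg(self):
        """Add is commutative and the branches share weights."""
        net = build_model(tiny_model_spec())
        rng = np.random.default_rng(1)
        a, b = rng.random((4, 6, 8, 3)), rng.random((4, 6, 8, 3))
        assert np.allclose(net.forward(a, b).ppg, net.forward(b, a).ppg)

    def test_output_length_tracks_frame_count(self):
        net = build_model(tiny_model_spec())
        for t in (2, 7, 33):
            x = np.zeros((t, 6, 8, 3))
            pred = net.forward(x, x)
            assert pred.ppg.shape == (t,) and pred.respiration.shape == (t,)

    def test_budget_deviation_warns(self):
        with pytest.warns(UserWarning, match="deviates"):
            build_model(tiny_model_spec(reference_budget=1e6))


class TestParameterCount:
    def test_multitask_budget(self):
        n = count_parameters(build_model(ModelSpec.default_multitask()))
        assert round(n / 1e6, 2) == round(MULTITASK_PARAM_BUDGET / 1e6, 2)

    def test_single_task_budget(self):
        n = count_parameters(build_model(ModelSpec.default_single_task()))
        assert round(n / 1e6, 2) == round(SINGLE_TASK_PARAM_BUDGET / 1e6, 2)

    def test_dense_layer_count(self):
        layer = nn.Dense(7, 3, np.random.default_rng(0))
        assert sum(p.size for p in layer.params()) == 7 * 3 + 3

    def test_shared_parameters_counted_once(self):
        net = build_model(tiny_model_spec())
        ids = [id(p) for p in net.parameters()]
        assert len(ids) == len(set(ids))
        # the two branch passes use the same layer objects
        x = np.random.default_rng(0).random((3, 6, 8, 3))
        net.forward(x, x)
        assert count_parameters(net) == sum(p.size for p in net.parameters())

    def test_single_task_is_mts_without_resp_head(self):
        mts = build_model(tiny_model_spec(multitask=True))
        single = build_model(tiny_model_spec(multitask=False))
        resp_params = sum(
            p.size
            for layer in (mts.resp_hidden, mts.resp_out)
            for p in layer.params()
        )
        assert count_parameters(mts) - count_parameters(single) == resp_params


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """End-to-end analytic gradients vs central finite differences."""
        spec = tiny_model_spec(n_frames=6, seed=3)
        net = build_model(spec)
        rng = np.random.default_rng(0)
        f, c = rng.random((6, 6, 8, 3)), rng.random((6, 6, 8, 3))
        ppg_t, resp_t = rng.random(6), rng.random(6)

        def total_loss():
            pred = net.forward(f, c)
            net._cache = None
            return (pearson_loss_grad(ppg_t, pred.ppg)[0]
                    + pearson_loss_grad(resp_t, pred.respiration)[0])

        pred = net.forward(f, c)
        _, g_ppg = pearson_loss_grad(ppg_t, pred.ppg)
        _, g_resp = pearson_loss_grad(resp_t, pred.respiration)
        net.zero_grad()
        net.backward(g_ppg, g_resp)

        eps = 1e-6
        for param in net.parameters():
            flat = param.value.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = total_loss()
                flat[i] = orig - eps
                lm = total_loss()
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = param.grad.ravel()[i]
                assert numeric == pytest.approx(analytic, rel=1e-3, abs=1e-7), param.name


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tmp_path):
        net = build_model(tiny_model_spec(seed=9))
        x = np.random.default_rng(0).random((4, 6, 8, 3))
        before = net.forward(x, x).ppg
        net.save(tmp_path / "ckpt.npz")
        restored = type(net).load(tmp_path / "ckpt.npz")
        assert restored.spec == net.spec
        assert np.allclose(restored.forward(x, x).ppg, before)

    def test_missing_checkpoint_raises(self, tmp_path):
        from siamvitals.model import SiameseVitalsNet

        with pytest.raises(FileNotFoundError):
            SiameseVitalsNet.load(tmp_path / "nope.npz")
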