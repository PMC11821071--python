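"""Layer primitives: hand-derived values, brute-force oracles, invariants."""

import numpy as np
import pytest
from scipy.signal import correlate

from fgdae._autodiff import Tensor
from fgdae.layers import (
    AttentionParams,
    GatedLayerParams,
    InstanceNormParams,
    ResidualGateParams,
    SelfONNParams,
    channel_attention_forward,
    gated_deconv_forward,
    gated_selfonn_forward,
    instance_norm_forward,
    residual_gate_forward,
    selfonn1d_forward,
)


def _selfonn(q, cin, cout, K, W=None, b=None):
    Wa = np.zeros((q, K, cin, cout)) if W is None else np.asarray(W, dtype=float)
    ba = np.zeros(cout) if b is None else np.asarray(b, dtype=float)
    return SelfONNParams(Tensor(Wa), Tensor(ba))


def _brute_selfonn(x, p):
    """Independent oracle: direct polynomial-convolution loops."""
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T  # (L, Cin)
    L, cin = x.shape
    q, K, _, cout = p.W.shape
    off = K // 2
    y = np.zeros((L, cout))
    for t in range(L):
        for co in range(cout):
            acc = p.b.data[co]
            for n in range(1, q + 1):
                for k in range(K):
                    src = t + k - off
                    if 0 <= src < L:
                        for ci in range(cin):
                            acc += p.W.data[n - 1, k, ci, co] * x[src, ci] ** n
            y[t, co] = acc
    return y


class TestSelfONN:
    def test_higher_orders_with_zero_weights_vanish(self, rng):
        x = rng.standard_normal((20, 2))
        W1 = rng.standard_normal((1, 9, 2, 3))
        W3 = np.concatenate([W1, np.zeros((2, 9, 2, 3))])
        b = rng.standard_normal(3)
        y1 = selfonn1d_forward(x, _selfonn(1, 2, 3, 9, W1, b))
        y3 = selfonn1d_forward(x, _selfonn(3, 2, 3, 9, W3, b))
        assert np.allclose(y1, y3)

    def test_identity_kernel_passes_signal_through(self, rng):
        W = np.zeros((1, 9, 1, 1))
        W[0, 4, 0, 0] = 1.0  # centre tap
        x = rng.standard_normal(32)
        y = selfonn1d_forward(x, _selfonn(1, 1, 1, 9, W))
        assert np.allclose(y, x)

    def test_pointwise_polynomial_hand_value(self):
        # y = 0.1 + 0.5 x + 0.25 x^2 evaluated per sample
        W = np.zeros((2, 1, 1, 1))
        W[0, 0, 0, 0], W[1, 0, 0, 0] = 0.5, 0.25
        y = selfonn1d_forward(np.array([1.0, 2.0]), _selfonn(2, 1, 1, 1, W, [0.1]))
        assert np.allclose(y, [0.85, 2.1])

    @pytest.mark.parametrize("q,cin,cout,L", [(1, 1, 1, 8), (2, 2, 3, 12), (4, 3, 2, 16), (3, 4, 4, 32)])
    def test_matches_bruteforce_oracle(self, rng, q, cin, cout, L):
        p = SelfONNParams.init(q, cin, cout, 9, rng, np.float64)
        x = rng.standard_normal((L, cin))
        y = selfonn1d_forward(x, p)
        ref = _brute_selfonn(x, p)
        assert np.abs(y - ref).max() / max(np.abs(ref).max(), 1) < 1e-6

    def test_q1_equals_plain_convolution(self, rng):
        """Order-1 self-ONN is exactly an ordinary convolution (scipy oracle)."""
        p = SelfONNParams.init(1, 2, 3, 9, rng, np.float64)
        x = rng.standard_normal((40, 2))
        y = selfonn1d_forward(x, p)
        ref = np.zeros((40, 3))
        for co in range(3):
            for ci in range(2):
                # scipy 'same' correlation per channel pair
                ref[:, co] += correlate(x[:, ci], p.W.data[0, :, ci, co], mode="same")
            ref[:, co] += p.b.data[co]
        assert np.abs(y - ref).max() < 1e-10

    def test_rejects_nonfinite_input(self):
        p = _selfonn(1, 1, 1, 9)
        with pytest.raises(ValueError):
            selfonn1d_forward(np.array([1.0, np.nan]), p)

    def test_rejects_invalid_order(self):
        with pytest.raises(ValueError):
            _selfonn(0, 1, 1, 9)


class TestGatedSelfONN:
    def _gp(self, in_W, in_b, gate_W, gate_b, q=1, cin=1, cout=1, K=1):
        return GatedLayerParams(
            _selfonn(q, cin, cout, K, in_W, in_b),
            _selfonn(q, cin, cout, K, gate_W, gate_b),
        )

    def test_zero_gate_halves_input_path(self, rng):
        Wi = rng.standard_normal((1, 9, 1, 2))
        gp = GatedLayerParams(
            _selfonn(1, 1, 2, 9, Wi), _selfonn(1, 1, 2, 9, np.zeros((1, 9, 1, 2)))
        )
        x = rng.standard_normal(16)
        feat = selfonn1d_forward(x, gp.input_path)
        assert np.allclose(gated_selfonn_forward(x, gp), 0.5 * feat)

    def test_saturated_gate_passes_input_path(self, rng):
        Wi = rng.standard_normal((1, 9, 1, 1))
        gp = GatedLayerParams(
            _selfonn(1, 1, 1, 9, Wi),
            _selfonn(1, 1, 1, 9, np.zeros((1, 9, 1, 1)), [20.0]),
        )
        x = rng.standard_normal(16)
        feat = np.asarray(selfonn1d_forward(x, gp.input_path))
        y = np.asarray(gated_selfonn_forward(x, gp))
        assert np.abs(y - feat).max() / np.abs(feat).max() < 1e-8

    def test_hand_value_unit_gate(self):
        gp = self._gp([[[[1.0]]]], [0.0], [[[[0.0]]]], [0.0])
        y = gated_selfonn_forward(np.array([2.0, -4.0]), gp)
        assert np.allclose(y, [1.0, -2.0])

    def test_mismatched_paths_rejected(self):
        with pytest.raises(ValueError):
            GatedLayerParams(_selfonn(1, 1, 2, 9), _selfonn(1, 1, 3, 9))


class TestGatedDeconv:
    def test_output_length_is_stride_times_input(self, rng):
        gp = GatedLayerParams(
            SelfONNParams.init(1, 2, 3, 9, rng), SelfONNParams.init(1, 2, 3, 9, rng)
        )
        y = gated_deconv_forward(rng.standard_normal((16, 2)), gp, stride=2)
        assert y.shape == (32, 3)

    def test_zero_gate_halves_transpose_conv(self, rng):
        Wi = rng.standard_normal((1, 9, 1, 1))
        gp = GatedLayerParams(
            _selfonn(1, 1, 1, 9, Wi), _selfonn(1, 1, 1, 9, np.zeros((1, 9, 1, 1)))
        )
        x = rng.standard_normal(8)
        y = gated_deconv_forward(x, gp, stride=2)
        gp_sat = GatedLayerParams(
            _selfonn(1, 1, 1, 9, Wi), _selfonn(1, 1, 1, 9, np.zeros((1, 9, 1, 1)), [30.0])
        )
        full = gated_deconv_forward(x, gp_sat, stride=2)
        assert np.allclose(y, 0.5 * full, atol=1e-7)

    def test_degenerate_kernel_hand_value(self):
        gp = GatedLayerParams(
            _selfonn(1, 1, 1, 1, [[[[2.0]]]]), _selfonn(1, 1, 1, 1, [[[[0.0]]]])
        )
        y = gated_deconv_forward(np.array([1.0, 3.0]), gp, stride=1)
        assert np.allclose(y, [1.0, 3.0])


class TestChannelAttention:
    def test_zero_params_make_unit_mask(self, rng):
        ap = AttentionParams(Tensor(np.zeros(3)), Tensor(np.zeros(1)))
        x = rng.standard_normal((10, 4))
        assert np.allclose(channel_attention_forward(x, ap), x)

    def test_mask_lies_strictly_inside_zero_two(self, rng):
        ap = AttentionParams.init(rng, dtype=np.float64)
        x = rng.standard_normal((16, 6)) * 5
        y = np.asarray(channel_attention_forward(x, ap))
        omega = y / np.where(np.abs(x) < 1e-12, 1.0, x)
        valid = np.abs(x) > 1e-12
        assert (omega[valid] > 0).all() and (omega[valid] < 2).all()

    def test_symmetric_descriptors_give_unit_mask(self):
        # xmax = 1, xavg = -1 and a centre-tap kernel: sigma(1)+sigma(-1) = 1
        ap = AttentionParams(Tensor(np.array([0.0, 1.0, 0.0])), Tensor(np.zeros(1)))
        x = np.array([[1.0], [-3.0]])
        assert np.allclose(channel_attention_forward(x, ap), x)


class TestResidualGate:
    def test_zero_convs_halve_input(self, rng):
        rp = ResidualGateParams.init(3, rng)
        for t in (rp.Win, rp.Wres, rp.bin, rp.bres):
            t.data[:] = 0
        x = rng.standard_normal((8, 3))
        assert np.allclose(residual_gate_forward(x, rng.standard_normal((8, 3)), rp), 0.5 * x)

    def test_saturated_mask_ignores_skip(self, rng):
        rp = ResidualGateParams.init(1, rng)
        rp.Win.data[:] = 0
        rp.Wres.data[:] = 0
        rp.bin.data[:] = 30.0
        rp.bres.data[:] = 0
        x = rng.standard_normal((8, 1))
        y = residual_gate_forward(x, rng.standard_normal((8, 1)) * 100, rp)
        assert np.abs(np.asarray(y) - x).max() < 1e-8

    def test_zero_input_stays_zero(self, rng):
        rp = ResidualGateParams.init(1, rng)
        rp.Win.data[:] = 1.0
        rp.Wres.data[:] = 0.0
        y = residual_gate_forward(np.zeros((1, 1)), rng.standard_normal((1, 1)), rp)
        assert np.allclose(y, 0.0)

    def test_shape_mismatch_rejected(self, rng):
        rp = ResidualGateParams.init(2, rng)
        with pytest.raises(ValueError):
            residual_gate_forward(np.zeros((4, 2)), np.zeros((5, 2)), rp)


class TestInstanceNorm:
    def test_standardizes_each_channel(self, rng):
        p = InstanceNormParams.init(3, eps=1e-8, dtype=np.float64)
        x = rng.standard_normal((64, 3)) * 4 + 2
        y = np.asarray(instance_norm_forward(x, p))
        assert np.abs(y.mean(axis=0)).max() < 1e-9
        assert np.abs(y.std(axis=0) - 1).max() < 1e-4

    def test_constant_channel_maps_to_beta(self):
        p = InstanceNormParams(Tensor(np.ones(1)), Tensor(np.array([0.7])), eps=1e-3)
        y = instance_norm_forward(np.full((16, 1), 5.0), p)
        assert np.allclose(y, 0.7)

    def test_affine_hand_value(self):
        p = InstanceNormParams(Tensor(np.array([2.0])), Tensor(np.array([1.0])), eps=1e-12)
        y = instance_norm_forward(np.array([0.0, 2.0]), p)
        assert np.allclose(y, [-1.0, 3.0], atol=1e-5)


@pytest.mark.parametrize("training", [False])
def test_all_forwards_are_deterministic_at_inference(rng, training):
    gp = GatedLayerParams(SelfONNParams.init(2, 2, 4, 9, rng), SelfONNParams.init(2, 2, 4, 9, rng), 0.5)
    ap = AttentionParams.init(rng, 0.5)
    x = rng.standard_normal((32, 2))
    a = np.asarray(gated_selfonn_forward(x, gp, training=training))
    b = np.asarray(gated_selfonn_forward(x, gp, training=training))
    assert np.array_equal(a, b)
    xa = rng.standard_normal((32, 4))
    assert np.array_equal(
        np.asarray(channel_attention_forward(xa, ap)),
        np.asarray(channel_attention_forward(xa, ap)),
    )


def test_time_length_preserved_except_deconv(rng):
    for L, cin in [(16, 1), (32, 3)]:
        x = rng.standard_normal((L, cin))
        p = SelfONNParams.init(2, cin, 2, 9, rng)
        assert np.asarray(selfonn1d_forward(x, p)).shape[0] == L
        ap = AttentionParams.init(rng)
        assert np.asarray(channel_attention_forward(x, ap)).shape[0] == L
        gp = GatedLayerParams(SelfONNParams.init(1, cin, 2, 9, rng), SelfONNParams.init(1, cin, 2, 9, rng))
        assert np.asarray(gated_deconv_forward(x, gp, stride=2)).shape[0] == 2 * L
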