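"""Reference kernels against brute-force oracles and closed forms."""

import numpy as np
import pytest

from hierbanet import infer_shapes
from hierbanet.ops import (
    BatchNormParams,
    ConvParams,
    batch_norm,
    conv2d_same,
    dense_softmax,
    dropout,
    forward,
    global_average_pool,
    leaky_relu,
    max_pool,
    predict_class,
)


def conv2d_direct(x, f, bias, stride=1):
    """Nested-loop direct cross-correlation oracle with 'same' zero padding."""
    kh, kw, cin, cout = f.shape
    h, w = x.shape[:2]
    oh, ow = int(np.ceil(h / stride)), int(np.ceil(w / stride))
    pt = max((oh - 1) * stride + kh - h, 0) // 2
    pl = max((ow - 1) * stride + kw - w, 0) // 2
    out = np.zeros((oh, ow, cout))
    for oi in range(oh):
        for oj in range(ow):
            for oc in range(cout):
                acc = bias[oc]
                for ki in range(kh):
                    for kj in range(kw):
                        ii = oi * stride + ki - pt
                        jj = oj * stride + kj - pl
                        if 0 <= ii < h and 0 <= jj < w:
                            for ic in range(cin):
                                acc += x[ii, jj, ic] * f[ki, kj, ic, oc]
                out[oi, oj, oc] = acc
    return out


class TestConv:
    def test_identity_kernel(self, rng):
        x = rng.random((6, 6, 1))
        p = ConvParams(np.ones((1, 1, 1, 1)), np.zeros(1))
        np.testing.assert_allclose(conv2d_same(x, p), x)

    def test_zero_kernel_gives_constant_bias_plane(self, rng):
        x = rng.random((5, 5, 2))
        p = ConvParams(np.zeros((3, 3, 2, 4)), np.full(4, 2.5))
        np.testing.assert_allclose(conv2d_same(x, p), np.full((5, 5, 4), 2.5))

    @pytest.mark.parametrize("shape,k", [((5, 5, 2), 3), ((7, 4, 3), 5), ((9, 9, 3), 7), ((4, 4, 1), 1)])
    def test_matches_nested_loop_oracle(self, rng, shape, k):
        x = rng.standard_normal(shape)
        f = rng.standard_normal((k, k, shape[2], 3))
        b = rng.standard_normal(3)
        got = conv2d_same(x, ConvParams(f, b))
        want = conv2d_direct(x, f, b)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            conv2d_same(rng.random((4, 4, 2)), ConvParams(np.zeros((3, 3, 3, 1)), np.zeros(1)))


class TestBatchNorm:
    def test_centering_yields_zero(self):
        x = np.full((3, 3, 2), 5.0)
        p = BatchNormParams(b_m=[5.0, 5.0], b_v2=[1.0, 1.0], p1=[1.0, 1.0], p2=[0.0, 0.0])
        np.testing.assert_allclose(batch_norm(x, p), 0.0)

    def test_unit_input_zero_stats(self):
        # 1 / sqrt(0 + 0.001) with scale 1, shift 0
        x = np.ones((1, 1, 1))
        p = BatchNormParams(b_m=[0.0], b_v2=[0.0], p1=[1.0], p2=[0.0])
        np.testing.assert_allclose(batch_norm(x, p)[0, 0, 0], 31.6227766, rtol=1e-7)

    def test_zero_scale_gives_shift(self, rng):
        x = rng.random((4, 4, 3))
        p = BatchNormParams(b_m=np.zeros(3), b_v2=np.ones(3), p1=np.zeros(3), p2=np.full(3, 7.0))
        np.testing.assert_allclose(batch_norm(x, p), 7.0)

    def test_true_statistics_standardize(self, rng):
        x = rng.standard_normal((8, 8, 4)) * 3 + 1
        mean = x.mean(axis=(0, 1))
        var = x.var(axis=(0, 1))
        p = BatchNormParams(b_m=mean, b_v2=var, p1=np.ones(4), p2=np.zeros(4))
        out = batch_norm(x, p)
        assert np.abs(out.mean(axis=(0, 1))).max() < 1e-6

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            BatchNormParams(b_m=[0.0], b_v2=[-1.0], p1=[1.0], p2=[0.0])


class TestActivationPooling:
    @pytest.mark.parametrize("x,want", [(2.0, 2.0), (-1.0, -0.001), (0.0, 0.0)])
    def test_leaky_relu_branches(self, x, want):
        assert leaky_relu(np.array([[[x]]]))[0, 0, 0] == pytest.approx(want)

    def test_max_pool_window(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        np.testing.assert_allclose(max_pool(x), [[[4.0]]])

    def test_max_pool_halves_even_dims(self, rng):
        assert max_pool(rng.random((224, 224, 2))).shape == (112, 112, 2)

    def test_max_pool_ceils_odd_dims(self, rng):
        assert max_pool(rng.random((5, 7, 1))).shape == (3, 4, 1)

    def test_max_pool_constant_input(self):
        x = np.full((6, 6, 3), 1.5)
        np.testing.assert_allclose(max_pool(x), np.full((3, 3, 3), 1.5))

    def test_gap_is_spatial_mean(self, rng):
        x = rng.random((7, 7, 5))
        np.testing.assert_allclose(global_average_pool(x), x.sum(axis=(0, 1)) / 49)

    def test_gap_constant_plane(self):
        np.testing.assert_allclose(global_average_pool(np.full((4, 4, 2), 3.3)), [3.3, 3.3])


class TestHead:
    def test_uniform_logits_give_uniform_probs(self):
        probs = dense_softmax(np.zeros(10), np.zeros((10, 3)), np.zeros(3), 3)
        np.testing.assert_allclose(probs, 1 / 3)

    def test_shift_invariance(self, rng):
        feats = rng.random(6)
        W = rng.standard_normal((6, 3))
        a = dense_softmax(feats, W, np.zeros(3), 3)
        b = dense_softmax(feats, W, np.full(3, 10.0), 3)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_closed_form_softmax(self):
        # logits (0, ln 2, 0) -> (0.25, 0.5, 0.25)
        probs = dense_softmax(
            np.array([1.0]), np.array([[0.0, np.log(2.0), 0.0]]), np.zeros(3), 3
        )
        np.testing.assert_allclose(probs, [0.25, 0.5, 0.25], rtol=1e-12)

    def test_extent_mismatch_raises(self):
        with pytest.raises(ValueError):
            dense_softmax(np.zeros(4), np.zeros((5, 3)), np.zeros(3), 3)

    def test_probabilities_normalized(self, rng):
        probs = dense_softmax(rng.random(8), rng.standard_normal((8, 4)), rng.random(4), 4)
        assert probs.min() >= 0
        assert abs(probs.sum() - 1) < 1e-9

    def test_tie_breaks_to_lowest_index(self):
        assert predict_class(np.array([0.4, 0.4, 0.2])) == 0


class TestDropout:
    def test_inference_is_identity(self, rng):
        x = rng.random((4, 4, 2))
        np.testing.assert_array_equal(dropout(x, 0.2, training=False), x)

    def test_zero_rate_identity_in_training(self, rng):
        x = rng.random((4, 4, 2))
        np.testing.assert_array_equal(dropout(x, 0.0, training=True, rng=rng), x)

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            dropout(np.zeros((2, 2, 1)), rate=1.0)

    def test_kept_fraction_near_expectation(self):
        rng = np.random.default_rng(42)
        x = np.ones((100, 100, 4))
        out = dropout(x, 0.2, training=True, rng=rng)
        kept = (out > 0).mean()
        se = np.sqrt(0.2 * 0.8 / x.size)
        assert abs(kept - 0.8) < 3 * se
        # inverted scaling preserves the expectation
        assert abs(out.mean() - 1.0) < 0.01


class TestForward:
    def test_output_is_probability_vector(self, tiny_graph, tiny_params, rng):
        probs = forward(tiny_graph, tiny_params, rng.random((32, 32, 3)))
        assert probs.shape == (3,)
        assert abs(probs.sum() - 1) < 1e-9

    def test_deterministic_in_inference(self, tiny_graph, tiny_params, rng):
        img = rng.random((32, 32, 3))
        a = forward(tiny_graph, tiny_params, img)
        b = forward(tiny_graph, tiny_params, img)
        np.testing.assert_array_equal(a, b)

    def test_activation_shapes_match_inference(self, tiny_graph, tiny_params, rng):
        _, acts = forward(tiny_graph, tiny_params, rng.random((32, 32, 3)), return_activations=True)
        shapes = infer_shapes(tiny_graph)
        for layer in tiny_graph.layers:
            got = acts[layer.name].shape
            want = shapes[layer.name].as_tuple()
            if len(got) == 1:  # vector-valued head layers
                want = (want[2],)
            assert got == want, layer.name

    def test_missing_params_raise(self, tiny_graph, tiny_params, rng):
        broken = {k: v for k, v in tiny_params.items() if k != "Base_Conv1"}
        with pytest.raises(KeyError, match="Base_Conv1"):
            forward(tiny_graph, broken, rng.random((32, 32, 3)))
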