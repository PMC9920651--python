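"""Architecture tests: causal padding, dilated convolution against a
brute-force oracle, receptive fields, residual blocks, full forward."""

import numpy as np
import pytest

from ecgtcn import (TCNNetwork, TCNSpec, causal_pad, dilated_causal_conv,
                    load_checkpoint, measure_receptive_field,
                    receptive_field_layer, receptive_field_paper,
                    save_checkpoint)
from ecgtcn.nn import CausalConv1d
from ecgtcn.tcn import tcn_forward


def conv_oracle(x: np.ndarray, w: np.ndarray, bias: np.ndarray, d: int
                ) -> np.ndarray:
    """Brute-force double loop over time and taps; causal left padding."""
    out_c, in_c, k = w.shape
    n = x.shape[1]
    pad = (k - 1) * d
    xp = np.concatenate([np.zeros((in_c, pad)), x], axis=1)
    y = np.zeros((out_c, n))
    for o in range(out_c):
        for t in range(n):
            acc = bias[o]
            for j in range(k):
                for i in range(in_c):
                    acc += w[o, i, j] * xp[i, pad + t - d * j]
            y[o, t] = acc
    return y


class TestCausalPad:
    def test_pads_left_with_k_minus_1_times_d_zeros(self):
        out = causal_pad(np.array([1.0, 2.0, 3.0]), k=2, d=1)
        np.testing.assert_array_equal(out, [0, 1, 2, 3])

    def test_single_tap_is_identity(self):
        np.testing.assert_array_equal(causal_pad(np.array([5.0, 5.0]), 1, 7),
                                      [5, 5])

    def test_dilated_pad_length_and_alignment(self):
        x = np.arange(140.0)
        out = causal_pad(x, k=3, d=4)
        assert out.shape == (148,)
        assert not out[:8].any()
        np.testing.assert_array_equal(out[8:], x)

    @pytest.mark.parametrize("k,d", [(0, 1), (1, 0), (-2, 3)])
    def test_rejects_nonpositive_arguments(self, k, d):
        with pytest.raises(ValueError):
            causal_pad(np.zeros(4), k, d)


class TestDilatedCausalConv:
    def test_single_tap_identity(self):
        x = np.array([3.0, -1.0, 4.0])
        np.testing.assert_array_equal(dilated_causal_conv(x, np.array([1.0])), x)

    def test_two_tap_running_sum(self):
        out = dilated_causal_conv(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0]))
        np.testing.assert_array_equal(out, [1, 3, 5])

    def test_unpadded_output_length_n_minus_k_plus_1(self):
        out = dilated_causal_conv(np.zeros((1, 1, 10)), np.ones((1, 1, 4)),
                                  pad=False)
        assert out.shape[2] == 10 - 4 + 1

    def test_matches_bruteforce_oracle_on_random_cases(self):
        """>=1000 random (n<=64, k<=8, d<=8) cases agree to 1e-10."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            n = int(rng.integers(1, 65))
            k = int(rng.integers(1, 9))
            d = int(rng.integers(1, 9))
            in_c = int(rng.integers(1, 4))
            out_c = int(rng.integers(1, 4))
            x = rng.normal(size=(in_c, n))
            w = rng.normal(size=(out_c, in_c, k))
            b = rng.normal(size=out_c)
            got = dilated_causal_conv(x[None], w, b, dilation=d)[0]
            np.testing.assert_allclose(got, conv_oracle(x, w, b, d), atol=1e-10)
            checked += 1

    def test_channel_mismatch_raises(self):
        with pytest.raises(ValueError, match="channels"):
            dilated_causal_conv(np.zeros((1, 2, 8)), np.ones((1, 3, 2)))

    def test_layer_output_never_depends_on_future(self):
        """Exact-zero difference when perturbing a strictly later input."""
        rng = np.random.default_rng(0)
        layer = CausalConv1d(1, 2, kernel_size=3, dilation=2, rng=rng)
        x = rng.normal(size=(1, 1, 20))
        base = layer.forward(x)
        xp = x.copy()
        xp[0, 0, 11] += 5.0
        out = layer.forward(xp)
        assert (out[:, :, :11] == base[:, :, :11]).all()


class TestReceptiveField:
    @pytest.mark.parametrize("l,k,expected", [(1, 1, 0), (4, 2, 16), (3, 3, 16)])
    def test_stack_formula(self, l, k, expected):
        assert receptive_field_paper(l, k) == expected

    @pytest.mark.parametrize("d,k,expected", [(8, 3, 16), (1, 2, 1)])
    def test_per_layer_formula(self, d, k, expected):
        assert receptive_field_layer(d, k) == expected

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            receptive_field_paper(0, 2)

    def test_measured_field_of_single_conv(self):
        rng = np.random.default_rng(1)
        layer = CausalConv1d(1, 1, kernel_size=2, dilation=1, rng=rng)
        got = measure_receptive_field(layer, position=10, x=np.zeros((1, 1, 16)))
        assert got == 2

    def test_measured_field_grows_with_block_count(self, ):
        fields = []
        for n_blocks in (1, 2, 3):
            spec = TCNSpec.build(n_blocks, 2, [2] * n_blocks, dropout=0.0,
                                 num_classes=2, input_length=32)
            net = TCNNetwork(spec, seed=5)
            fields.append(measure_receptive_field(net, position=31))
        assert fields == sorted(fields)
        assert fields[0] < fields[-1]

    def test_position_out_of_range(self, tiny_spec):
        with pytest.raises(ValueError, match="position"):
            measure_receptive_field(TCNNetwork(tiny_spec, seed=0), position=99)


class TestResidualBlock:
    def test_inference_is_deterministic(self, tiny_spec):
        net = TCNNetwork(tiny_spec, seed=3)
        x = np.random.default_rng(4).normal(size=(2, 1, 16))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_first_block_expands_channels(self, tiny_spec):
        net = TCNNetwork(tiny_spec, seed=0)
        x = np.zeros((2, 1, 16))
        out = net.blocks[0].forward(x)
        assert out.shape == (2, 3, 16)

    def test_zero_weights_stay_finite(self, tiny_spec):
        net = TCNNetwork(tiny_spec, seed=0)
        for p in net.params():
            p.value[...] = 0.0
        out = net.blocks[0].forward(np.random.default_rng(0).normal(size=(2, 1, 16)))
        assert np.isfinite(out).all()

    def test_length_preserved_for_all_published_configs(self):
        from ecgtcn import experiment_preset

        x = np.random.default_rng(9).normal(size=(1, 1, 140))
        for name in ("1", "3", "9"):  # 4-, 5- and 3-block variants
            net = TCNNetwork(experiment_preset(name).spec, seed=0)
            h = x
            for block in net.blocks:
                h = block.forward(h)
                assert h.shape[2] == 140

    def test_dropout_identity_in_inference(self, tiny_spec):
        spec = TCNSpec.build(2, 3, (2, 3), dropout=0.5, num_classes=3,
                             input_length=16)
        net = TCNNetwork(spec, seed=0)
        x = np.random.default_rng(1).normal(size=(2, 1, 16))
        np.testing.assert_array_equal(net.forward(x, training=False),
                                      net.forward(x, training=False))


class TestFullForward:
    def test_probabilities_sum_to_one(self, tiny_spec):
        net = TCNNetwork(tiny_spec, seed=0)
        p = net.predict_proba(np.random.default_rng(0).normal(size=(7, 1, 16)))
        assert p.shape == (7, 3)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_uniform_logits_give_uniform_probabilities(self, tiny_spec):
        net = TCNNetwork(tiny_spec, seed=0)
        net.head.W.value[...] = 0.0
        net.head.b.value[...] = 0.0
        p = net.predict_proba(np.random.default_rng(0).normal(size=(3, 1, 16)))
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-12)

    def test_published_batch_shape(self):
        """A batch of 20 length-140 beats through the headline architecture."""
        from ecgtcn import experiment_preset

        spec = experiment_preset("1").spec
        p = tcn_forward(np.random.default_rng(0).normal(size=(20, 1, 140)),
                        spec, seed=0)
        assert p.shape == (20, 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_full_model_causality_is_exact(self, tiny_spec):
        net = TCNNetwork(tiny_spec, seed=2)
        x = np.random.default_rng(3).normal(size=(1, 1, 16))
        base = net.features(x)
        xp = x.copy()
        xp[0, 0, 9] += 1.0
        out = net.features(xp)
        assert (out[:, :, :9] == base[:, :, :9]).all()

    def test_wrong_length_raises(self, tiny_spec):
        with pytest.raises(ValueError, match="length"):
            TCNNetwork(tiny_spec, seed=0).forward(np.zeros((1, 1, 99)))


class TestSpecValidation:
    def test_builder_checks_kernel_count(self):
        with pytest.raises(ValueError, match="kernel"):
            TCNSpec.build(3, 8, (2, 4))

    def test_dilations_double_per_block(self):
        spec = TCNSpec.build(5, 4, (2, 2, 2, 2, 2))
        assert spec.dilations == (1, 2, 4, 8, 16)

    def test_skip_projection_only_where_channels_change(self):
        spec = TCNSpec.build(3, 8, (2, 4, 6))
        assert [b.skip_projection for b in spec.blocks] == [True, False, False]

    def test_conv_spec_rejects_nonpositive(self):
        from ecgtcn import ConvLayerSpec

        with pytest.raises(ValueError):
            ConvLayerSpec(kernel_size=0, in_channels=1, out_channels=1)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tiny_spec, tmp_path):
        net = TCNNetwork(tiny_spec, seed=11)
        x = np.random.default_rng(0).normal(size=(3, 1, 16))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net, extra={"note": "test"})
        loaded, extra = load_checkpoint(path)
        assert extra == {"note": "test"}
        np.testing.assert_array_equal(loaded.predict_proba(x),
                                      net.predict_proba(x))
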