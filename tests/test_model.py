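"""Architecture arithmetic, the 3D convolution, and the trainable network."""

import numpy as np
import pytest
from scipy.ndimage import convolve as nd_convolve

from hemoct.model import (
    ArchitectureSpec,
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    MaxPool3D,
    Network,
    conv3d_forward,
    count_parameters,
    layer_output_shapes,
    load_checkpoint,
    save_checkpoint,
    table2_spec,
)


def scipy_conv_oracle(x, kernels, biases):
    """Independent oracle: per-map triple-sum convolution via scipy.ndimage."""
    w, l, d, ci = x.shape
    co = kernels.shape[4]
    out = np.zeros((w, l, d, co))
    for j in range(co):
        for i in range(ci):
            out[..., j] += nd_convolve(
                x[..., i], kernels[..., i, j], mode="constant", cval=0.0
            )
        out[..., j] += biases[j]
    return out


def nested_loop_oracle(x, kernels, biases):
    """Literal triple-nested summation S(l,m,n) = sum_abc I(l-a,m-b,n-c) K(a,b,c)."""
    w, l_, d, ci = x.shape
    k1, k2, k3, _, co = kernels.shape
    r1, r2, r3 = k1 // 2, k2 // 2, k3 // 2
    out = np.zeros((w, l_, d, co))
    for j in range(co):
        for l in range(w):
            for m in range(l_):
                for n in range(d):
                    s = 0.0
                    for i in range(ci):
                        for a in range(-r1, r1 + 1):
                            for b in range(-r2, r2 + 1):
                                for c in range(-r3, r3 + 1):
                                    li, mi, ni = l - a, m - b, n - c
                                    if 0 <= li < w and 0 <= mi < l_ and 0 <= ni < d:
                                        s += x[li, mi, ni, i] * kernels[a + r1, b + r2, c + r3, i, j]
                    out[l, m, n, j] = s + biases[j]
    return out


class TestShapeArithmetic:
    def test_default_architecture_output_column(self):
        """The printed output-size column, including ceiling pooling and 25088."""
        shapes = layer_output_shapes(table2_spec(n_classes=2), (50, 50, 28))
        assert shapes == [
            (50, 50, 28, 32),
            (25, 25, 14, 32),
            (25, 25, 14, 64),
            (13, 13, 7, 64),
            (13, 13, 7, 128),
            (7, 7, 4, 128),
            25088,
            1024,
            2,
        ]

    def test_ceiling_pooling_chain(self):
        d = 25
        chain = [d]
        for _ in range(3):
            d = -(-d // 2)
            chain.append(d)
        assert chain == [25, 13, 7, 4]

    def test_pooling_a_unit_dim_stays_unit(self):
        spec = table2_spec(n_classes=2, filters=(4,), dense_units=8)
        shapes = layer_output_shapes(spec, (1, 4, 1))
        assert shapes[1] == (1, 2, 1, 4)

    def test_parameter_count_matches_hand_sum(self):
        spec = table2_spec(n_classes=2)
        hand = (
            (27 * 1 * 32 + 32)
            + (27 * 32 * 64 + 64)
            + (27 * 64 * 128 + 128)
            + (25088 * 1024 + 1024)
            + (1024 * 2 + 2)
        )
        assert count_parameters(spec, (50, 50, 28)) == hand
        assert Network(spec, seed=0).n_parameters() == hand

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="first layer"):
            ArchitectureSpec((Flatten(), Dense(2)), n_classes=2)
        with pytest.raises(ValueError, match="units == n_classes"):
            ArchitectureSpec((Conv3D(2), Flatten(), Dense(3)), n_classes=2)
        with pytest.raises(ValueError):
            Conv3D(4, kernel=(2, 2, 2))  # even kernels have no centered padding
        with pytest.raises(ValueError):
            Dropout(1.0)

    def test_spec_dict_round_trip(self):
        spec = table2_spec(n_classes=4, filters=(8, 16), dense_units=64)
        assert ArchitectureSpec.from_dict(spec.to_dict()) == spec


class TestConv3dForward:
    def test_identity_kernel(self, rng):
        x = rng.normal(size=(5, 4, 3, 2))
        k = np.zeros((3, 3, 3, 2, 2))
        k[1, 1, 1, 0, 0] = 1.0
        k[1, 1, 1, 1, 1] = 1.0
        out = conv3d_forward(x, k, np.zeros(2), activation="none")
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_zero_kernel_relu_of_bias(self, rng):
        x = rng.normal(size=(4, 4, 4, 1))
        k = np.zeros((3, 3, 3, 1, 2))
        out = conv3d_forward(x, k, np.array([2.0, -3.0]), activation="relu")
        assert np.all(out[..., 0] == 2.0)
        assert np.all(out[..., 1] == 0.0)

    def test_matches_scipy_triple_sum(self, rng):
        for _ in range(20):
            ci, co = rng.integers(1, 3, size=2)
            shape = tuple(rng.integers(3, 8, size=3)) + (ci,)
            x = rng.normal(size=shape)
            k = rng.normal(size=(3, 3, 3, ci, co))
            b = rng.normal(size=co)
            got = conv3d_forward(x, k, b, activation="none")
            np.testing.assert_allclose(got, scipy_conv_oracle(x, k, b), atol=1e-10)

    def test_matches_literal_nested_sum(self, rng):
        x = rng.normal(size=(4, 3, 3, 2))
        k = rng.normal(size=(3, 3, 3, 2, 2))
        b = rng.normal(size=2)
        got = conv3d_forward(x, k, b, activation="none")
        np.testing.assert_allclose(got, nested_loop_oracle(x, k, b), atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        x = rng.normal(size=(4, 4, 4, 2))
        k = rng.normal(size=(3, 3, 3, 3, 2))
        with pytest.raises(ValueError, match="input maps"):
            conv3d_forward(x, k, np.zeros(2))


@pytest.fixture
def tiny_spec():
    return ArchitectureSpec(
        (Conv3D(3), MaxPool3D(), Conv3D(4), MaxPool3D(), Flatten(), Dense(6), Dropout(0.2), Dense(2)),
        n_classes=2,
    )


class TestNetwork:
    def test_zero_init_gives_tied_logits(self, tiny_spec):
        net = Network(tiny_spec, input_shape=(6, 6, 4), seed=0, init_std=0.0)
        logits = net.forward(np.zeros((1, 6, 6, 4)))
        assert logits.shape == (1, 2)
        assert logits[0, 0] == logits[0, 1]

    def test_repeated_input_gives_identical_rows(self, tiny_spec, rng):
        net = Network(tiny_spec, input_shape=(6, 6, 4), seed=1)
        x = rng.normal(size=(6, 6, 4))
        logits = net.forward(np.stack([x, x, x]))
        np.testing.assert_array_equal(logits[0], logits[1])
        np.testing.assert_array_equal(logits[1], logits[2])

    def test_batch_permutation_equivariant(self, tiny_spec, rng):
        net = Network(tiny_spec, input_shape=(6, 6, 4), seed=1)
        X = rng.normal(size=(5, 6, 6, 4))
        perm = rng.permutation(5)
        np.testing.assert_allclose(
            net.forward(X)[perm], net.forward(X[perm]), rtol=1e-5, atol=1e-6
        )

    def test_wrong_input_shape_names_expected(self, tiny_spec, rng):
        net = Network(tiny_spec, input_shape=(6, 6, 4), seed=0)
        with pytest.raises(ValueError, match=r"\(N, 6, 6, 4\)"):
            net.forward(rng.normal(size=(2, 5, 6, 4)))

    def test_relu_activations_nonnegative(self, tiny_spec, rng):
        net = Network(tiny_spec, input_shape=(6, 6, 4), seed=2)
        acts = net.layer_activations(rng.normal(size=(2, 6, 6, 4)))
        for layer_spec, h in acts[:-1]:  # final dense emits raw logits
            assert np.all(h >= 0.0)

    def test_gradients_match_finite_differences(self, tiny_spec, rng):
        net = Network(tiny_spec, input_shape=(6, 6, 4), seed=3, dtype=np.float64)
        X = rng.normal(size=(3, 6, 6, 4))
        y = np.array([0, 1, 1])
        fixed = lambda: np.random.default_rng(99)  # same dropout mask each call
        net.loss_and_grads(X, y, rng=fixed())
        grads = {k: v.copy() for k, v in net.gradients.items()}
        params = net.parameters
        eps = 1e-6
        for name, arr in params.items():
            flat = arr.ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = net.loss_and_grads(X, y, rng=fixed())
                flat[idx] = old - eps
                lm = net.loss_and_grads(X, y, rng=fixed())
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert grads[name].ravel()[idx] == pytest.approx(num, abs=1e-7)

    def test_checkpoint_round_trip(self, tiny_spec, rng, tmp_path):
        net = Network(tiny_spec, input_shape=(6, 6, 4), seed=4)
        net.input_mean = rng.normal(size=(6, 6, 4, 1)).astype(np.float32)
        save_checkpoint(net, tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz")
        assert back.spec == net.spec
        x = rng.normal(size=(2, 6, 6, 4))
        np.testing.assert_array_equal(back.forward(x), net.forward(x))


def test_ceil_pooling_on_odd_dims_matches_shape_arithmetic(rng):
    spec = ArchitectureSpec((Conv3D(2), MaxPool3D(), Flatten(), Dense(2)), n_classes=2)
    net = Network(spec, input_shape=(5, 7, 3), seed=0)
    acts = net.layer_activations(rng.normal(size=(1, 5, 7, 3)))
    assert acts[1][1].shape == (1, 3, 4, 2, 2)


def test_pooling_takes_window_maximum():
    x = np.arange(4 * 4 * 2, dtype=float).reshape(1, 4, 4, 2, 1)
    spec = ArchitectureSpec((Conv3D(1), MaxPool3D(), Flatten(), Dense(2)), n_classes=2)
    net = Network(spec, input_shape=(4, 4, 2), seed=0)
    pooled = net.layers[1].forward(x, False, None)
    assert pooled[0, 0, 0, 0, 0] == x[0, :2, :2, :2, 0].max()
    assert pooled[0, 1, 1, 0, 0] == x[0, 2:, 2:, :2, 0].max()
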