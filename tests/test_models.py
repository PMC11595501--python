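import numpy as np
import pytest

from topodecode.models import (
    Conv3DLayerSpec,
    LSTMCellSpec,
    ModelGraph,
    build_model,
    conv3d_forward,
    lstm_step,
)
from topodecode.models.graph import Adam, softmax
from topodecode.models.layers import (
    Bidirectional,
    Conv3D,
    Dense,
    Dropout,
    LSTM,
    MaxPool3D,
    SequenceReshape,
)


# --- independent oracles -------------------------------------------------

def naive_conv3d(volume, weights, bias, activation):
    """Brute-force triple-sum evaluation of the 3D convolution."""
    d, h, w, cin = volume.shape
    p, q, r, _, cout = weights.shape
    vp = np.pad(
        volume,
        [((p - 1) // 2, p // 2), ((q - 1) // 2, q // 2),
         ((r - 1) // 2, r // 2), (0, 0)],
    )
    out = np.zeros((d, h, w, cout))
    for x in range(d):
        for y in range(h):
            for z in range(w):
                for j in range(cout):
                    s = bias[j]
                    for pp in range(p):
                        for qq in range(q):
                            for rr in range(r):
                                for m in range(cin):
                                    s += (
                                        weights[pp, qq, rr, m, j]
                                        * vp[x + pp, y + qq, z + rr, m]
                                    )
                    out[x, y, z, j] = s
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation == "tanh":
        return np.tanh(out)
    return out


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def naive_lstm_sequence(xs, cell):
    """Step-by-step evaluation of the gate equations on a sequence."""
    h = np.zeros(cell.units)
    c = np.zeros(cell.units)
    for x in xs:
        hx = np.concatenate([h, x])
        i = sigmoid(cell.W_i @ hx + cell.b_i)
        f = sigmoid(cell.W_f @ hx + cell.b_f)
        c = f * c + i * np.tanh(cell.W_c @ hx + cell.b_c)
        o = sigmoid(cell.W_o @ hx + cell.b_o)
        h = o * np.tanh(c)
    return h, c


# --- conv reference op ---------------------------------------------------

class TestConv3DForward:
    def test_zero_input_relu_gives_clamped_bias(self):
        w = np.zeros((3, 3, 3, 1, 2))
        b = np.array([0.7, -0.4])
        layer = Conv3DLayerSpec(2, weights=w, bias=b, activation="relu")
        out = conv3d_forward(np.zeros((4, 4, 4, 1)), layer)
        np.testing.assert_allclose(out[..., 0], 0.7)
        np.testing.assert_allclose(out[..., 1], 0.0)

    def test_identity_kernel(self, rng):
        w = np.zeros((3, 3, 3, 1, 1))
        w[1, 1, 1, 0, 0] = 1.0
        layer = Conv3DLayerSpec(
            1, weights=w, bias=np.zeros(1), activation="linear"
        )
        vol = rng.standard_normal((5, 5, 5, 1))
        np.testing.assert_allclose(conv3d_forward(vol, layer), vol, atol=1e-12)

    @pytest.mark.parametrize("shape", [(4, 4, 4, 1), (6, 5, 4, 2), (3, 6, 5, 3)])
    @pytest.mark.parametrize("activation", ["linear", "relu", "tanh"])
    def test_matches_naive_loop_oracle(self, rng, shape, activation):
        vol = rng.standard_normal(shape)
        w = rng.standard_normal((3, 3, 3, shape[-1], 2))
        b = rng.standard_normal(2)
        layer = Conv3DLayerSpec(2, weights=w, bias=b, activation=activation)
        got = conv3d_forward(vol, layer)
        expected = naive_conv3d(vol, w, b, activation)
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_channel_mismatch_errors(self, rng):
        layer = Conv3DLayerSpec(
            1,
            weights=rng.standard_normal((3, 3, 3, 2, 1)),
            bias=np.zeros(1),
        )
        with pytest.raises(ValueError):
            conv3d_forward(np.zeros((4, 4, 4, 3)), layer)

    def test_trainable_layer_matches_reference_op(self, rng):
        conv = Conv3D(3, 4, activation="relu")
        conv.init(rng)
        x = rng.standard_normal((2, 4, 5, 6, 3)).astype(np.float32)
        got = conv.forward(x)
        spec = Conv3DLayerSpec(
            4, weights=conv.params["W"], bias=conv.params["b"], activation="relu"
        )
        for n in range(2):
            np.testing.assert_allclose(
                got[n], conv3d_forward(x[n], spec), atol=1e-5
            )


# --- lstm reference op ---------------------------------------------------

class TestLSTMStep:
    def test_all_zero_weights(self):
        cell = LSTMCellSpec(units=3, input_dim=2)
        h, c = lstm_step(np.ones(2), np.zeros(3), np.zeros(3), cell)
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(h, 0.0)

    def test_forget_gate_saturation_preserves_memory(self):
        cell = LSTMCellSpec(units=2, input_dim=1, b_f=np.full(2, 60.0))
        c_prev = np.array([0.3, -1.2])
        _, c = lstm_step(np.zeros(1), np.zeros(2), c_prev, cell)
        np.testing.assert_allclose(c, c_prev, atol=1e-9)

    def test_matches_manual_equations(self, rng):
        units, dim = 4, 3
        cell = LSTMCellSpec(
            units=units,
            input_dim=dim,
            **{
                f"W_{g}": 0.3 * rng.standard_normal((units, units + dim))
                for g in "ifco"
            },
            **{f"b_{g}": 0.1 * rng.standard_normal(units) for g in "ifco"},
        )
        x = rng.standard_normal(dim)
        h_prev = rng.standard_normal(units) * 0.2
        c_prev = rng.standard_normal(units) * 0.2
        h, c = lstm_step(x, h_prev, c_prev, cell)
        # recompute by hand
        hx = np.concatenate([h_prev, x])
        i = sigmoid(cell.W_i @ hx + cell.b_i)
        f = sigmoid(cell.W_f @ hx + cell.b_f)
        c_ref = f * c_prev + i * np.tanh(cell.W_c @ hx + cell.b_c)
        o = sigmoid(cell.W_o @ hx + cell.b_o)
        h_ref = o * np.tanh(c_ref)
        np.testing.assert_allclose(c, c_ref, atol=1e-12)
        np.testing.assert_allclose(h, h_ref, atol=1e-12)
        assert ((i > 0) & (i < 1)).all() and ((f > 0) & (f < 1)).all()

    def test_dimension_mismatch(self):
        cell = LSTMCellSpec(units=2, input_dim=3)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(4), np.zeros(2), np.zeros(2), cell)

    def test_layer_matches_step_oracle_over_sequence(self, rng):
        units, dim, t = 5, 4, 3
        layer = LSTM(dim, units)
        layer.init(rng)
        wx, wh, b = layer.params["Wx"], layer.params["Wh"], layer.params["b"]
        u = units
        gates = {"i": 0, "f": 1, "c": 2, "o": 3}
        cell = LSTMCellSpec(
            units=units,
            input_dim=dim,
            **{
                f"W_{g}": np.hstack(
                    [wh[:, k * u : (k + 1) * u].T, wx[:, k * u : (k + 1) * u].T]
                )
                for g, k in gates.items()
            },
            **{f"b_{g}": b[k * u : (k + 1) * u] for g, k in gates.items()},
        )
        xs = rng.standard_normal((t, dim)).astype(np.float32)
        h_ref, _ = naive_lstm_sequence(xs, cell)
        h_got = layer.forward(xs[None].astype(np.float32))
        np.testing.assert_allclose(h_got[0], h_ref, atol=1e-6)


# --- layer gradients vs numeric differentiation --------------------------

def numeric_grad(f, arr, idx, eps):
    orig = arr[idx]
    arr[idx] = orig + eps
    lp = f()
    arr[idx] = orig - eps
    lm = f()
    arr[idx] = orig
    return (lp - lm) / (2 * eps)


class TestLayerGradients:
    def test_graph_gradients_match_numeric(self, rng):
        model = build_model(
            "bilstm", 2, input_shape=(8, 8, 8, 3), dropout_rate=0.0, seed=1
        )
        x = rng.standard_normal((4, 8, 8, 8, 3)).astype(np.float32)
        y = np.array([0, 1, 1, 0])
        checks = [
            (0, "W", (0, 1, 2, 1, 5)),
            (2, "W", (2, 0, 1, 10, 30)),
            (3, "Wx", (3, 100)),
            (4, "Wh", (5, 10)),
            (5, "W", (3, 1)),
            (5, "b", (0,)),
        ]
        for li, name, idx in checks:
            layer = model.param_layers()[li]
            model.loss_and_grads(x, y)
            analytic = layer.grads[name][idx]
            num = numeric_grad(
                lambda: model.evaluate_loss(x, y), layer.params[name], idx, 1e-2
            )
            assert analytic == pytest.approx(num, abs=2e-3), (li, name)

    def test_maxpool_gradient_routes_to_maxima(self):
        pool = MaxPool3D()
        x = np.arange(16, dtype=np.float32).reshape(1, 2, 2, 4, 1)
        out = pool.forward(x, training=True)
        np.testing.assert_array_equal(out.ravel(), [13.0, 15.0])
        dx = pool.backward(np.array([[[[[2.0], [3.0]]]]]))
        assert dx[0, 1, 1, 1, 0] == 2.0  # value 13
        assert dx[0, 1, 1, 3, 0] == 3.0  # value 15
        assert dx.sum() == 5.0

    def test_maxpool_gradient_splits_ties(self):
        pool = MaxPool3D()
        x = np.zeros((1, 2, 2, 2, 1), dtype=np.float32)
        pool.forward(x, training=True)
        dx = pool.backward(np.full((1, 1, 1, 1, 1), 8.0))
        np.testing.assert_allclose(dx, 1.0)  # 8 tied entries share evenly

    def test_dropout_inverted_scaling(self, rng):
        drop = Dropout(0.4)
        drop.rng = np.random.default_rng(0)
        x = np.ones((200, 50), dtype=np.float32)
        out = drop.forward(x, training=True)
        zero_frac = (out == 0).mean()
        assert zero_frac == pytest.approx(0.4, abs=0.05)
        assert out.mean() == pytest.approx(1.0, abs=0.05)
        np.testing.assert_array_equal(drop.forward(x, training=False), x)


# --- architecture --------------------------------------------------------

class TestBuildModel:
    def test_conv_stack_output_shape(self):
        model = build_model("lstm", 2)
        assert model.conv_output_shape() == (2, 8, 8, 64)

    def test_flatten_and_reshape_arithmetic(self):
        model = build_model("lstm", 2)
        d, h, w, c = model.conv_output_shape()
        assert d * h * w * c == 8192 == 16 * 512

    def test_bilstm_head_dimension(self):
        assert build_model("bilstm", 2).head_output_dim() == 128

    def test_probabilities_sum_to_one(self, rng):
        model = build_model("lstm", 3, input_shape=(8, 8, 8, 3), seed=0)
        x = rng.random((3, 8, 8, 8, 3)).astype(np.float32)
        probs = model.forward(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_invalid_variant(self):
        with pytest.raises(ValueError):
            build_model("gru", 2)

    def test_invalid_n_classes(self):
        with pytest.raises(ValueError):
            build_model("lstm", 1)

    def test_indivisible_input_shape_errors(self):
        with pytest.raises(ValueError, match="not divisible"):
            build_model("lstm", 2, input_shape=(12, 64, 64, 3))

    @pytest.mark.parametrize(
        "variant,expected",
        [("lstm", 218370), ("stack_lstm", 251394), ("bilstm", 366210)],
    )
    def test_parameter_counts_frozen(self, variant, expected):
        assert build_model(variant, 2).parameter_count() == expected

    @pytest.mark.parametrize("variant", ["lstm", "stack_lstm", "bilstm"])
    def test_parameter_count_formula(self, variant):
        # independent arithmetic: conv (27*cin+1)*cout; lstm 4*((f+u)*u+u)
        conv = sum(
            (27 * cin + 1) * cout
            for cin, cout in [(3, 16), (16, 32), (32, 64)]
        )
        lstm = lambda f, u: 4 * ((f + u) * u + u)
        heads = {
            "lstm": lstm(512, 64),
            "stack_lstm": lstm(512, 64) + lstm(64, 64),
            "bilstm": 2 * lstm(512, 64),
        }
        dense_in = 128 if variant == "bilstm" else 64
        expected = conv + heads[variant] + (dense_in + 1) * 2
        assert build_model(variant, 2).parameter_count() == expected

    def test_head_change_leaves_trunk_counts(self):
        counts = {}
        for variant in ("lstm", "stack_lstm", "bilstm"):
            model = build_model(variant, 2)
            counts[variant] = [
                l.parameter_count()
                for l in model.param_layers()
                if isinstance(l, Conv3D)
            ]
        assert counts["lstm"] == counts["stack_lstm"] == counts["bilstm"]

    def test_same_seed_same_weights(self):
        a = build_model("lstm", 2, seed=5)
        b = build_model("lstm", 2, seed=5)
        for la, lb in zip(a.param_layers(), b.param_layers()):
            for name in la.params:
                np.testing.assert_array_equal(la.params[name], lb.params[name])

    def test_weight_save_load_roundtrip(self, tmp_path, rng):
        model = build_model("stack_lstm", 2, input_shape=(8, 8, 8, 3), seed=0)
        x = rng.random((2, 8, 8, 8, 3)).astype(np.float32)
        ref = model.forward(x)
        path = tmp_path / "weights.npz"
        model.save_weights(path)
        other = build_model("stack_lstm", 2, input_shape=(8, 8, 8, 3), seed=99)
        assert not np.allclose(other.forward(x), ref)
        other.load_weights(path)
        np.testing.assert_array_equal(other.forward(x), ref)

    def test_input_shape_mismatch_errors(self, rng):
        model = build_model("lstm", 2, input_shape=(8, 8, 8, 3))
        with pytest.raises(ValueError, match="input"):
            model.forward(rng.random((1, 16, 64, 64, 3)).astype(np.float32))


class TestOptimization:
    def test_adam_reduces_loss_on_small_problem(self, rng):
        model = build_model("lstm", 2, input_shape=(8, 8, 8, 3), dropout_rate=0.0, seed=0)
        x = rng.standard_normal((8, 8, 8, 8, 3)).astype(np.float32)
        y = np.array([0, 1] * 4)
        opt = Adam(model, learning_rate=5e-3)
        first = model.loss_and_grads(x, y)
        for _ in range(30):
            model.loss_and_grads(x, y)
            opt.step()
        assert model.evaluate_loss(x, y) < first * 0.5

    def test_softmax_stability(self):
        probs = softmax(np.array([[1000.0, 0.0], [-1000.0, 0.0]]))
        assert np.isfinite(probs).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)
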