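"""Model assembly: the shared conv/pool trunk plus one of three heads."""

from __future__ import annotations

import numpy as np

from .layers import (
    Bidirectional,
    Conv3D,
    Dense,
    Dropout,
    Layer,
    LSTM,
    MaxPool3D,
    SequenceReshape,
)

__all__ = ["ModelGraph", "build_model", "Adam", "VARIANTS"]

VARIANTS = ("lstm", "stack_lstm", "bilstm")

CONV_FILTERS = (16, 32, 64)
LSTM_UNITS = 64
POOL = 2
N_POOLS = 3


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ModelGraph:
    """An executable computation graph for one architecture variant."""

    def __init__(
        self,
        variant: str,
        n_classes: int,
        input_shape: tuple[int, int, int, int],
        dropout_rate: float,
        layers: list[Layer],
        seed: int,
    ) -> None:
        self.variant = variant
        self.n_classes = n_classes
        self.input_shape = tuple(input_shape)
        self.dropout_rate = dropout_rate
        self.layers = layers
        self.seed = seed

    # -- execution -----------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model "
                f"input {self.input_shape}"
            )
        return x

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = self._check_input(x)
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities (softmax over the dense output)."""
        return softmax(self.logits(x, training=training))

    predict_proba = forward

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).argmax(axis=1)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean categorical cross-entropy; gradients stored on each layer."""
        x = self._check_input(x)
        y = np.asarray(y)
        logits = self.logits(x, training=True)
        n = logits.shape[0]
        probs = softmax(logits)
        loss = float(
            -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
        )
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = self.forward(x)
        n = probs.shape[0]
        return float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())

    # -- parameters ----------------------------------------------------

    def param_layers(self) -> list[Layer]:
        out: list[Layer] = []
        for layer in self.layers:
            out.extend(l for l in layer.param_layers() if l.params)
        return out

    def parameter_count(self) -> int:
        return sum(l.parameter_count() for l in self.param_layers())

    def reset_dropout_rng(self, seed: int) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(seed)

    def save_weights(self, path) -> None:
        arrays = {}
        for i, layer in enumerate(self.param_layers()):
            for name, value in layer.params.items():
                arrays[f"layer{i:02d}/{name}"] = value
        np.savez_compressed(path, **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as z:
            for i, layer in enumerate(self.param_layers()):
                for name in layer.params:
                    key = f"layer{i:02d}/{name}"
                    if z[key].shape != layer.params[name].shape:
                        raise ValueError(f"shape mismatch for {key}")
                    layer.params[name] = z[key].astype(np.float32)

    def get_config(self) -> dict:
        return {
            "variant": self.variant,
            "n_classes": self.n_classes,
            "input_shape": list(self.input_shape),
            "dropout": self.dropout_rate,
            "seed": self.seed,
        }

    # -- derived shapes ------------------------------------------------

    def conv_output_shape(self) -> tuple[int, int, int, int]:
        d, h, w, _ = self.input_shape
        f = POOL ** N_POOLS
        return (d // f, h // f, w // f, CONV_FILTERS[-1])

    def head_output_dim(self) -> int:
        return 2 * LSTM_UNITS if self.variant == "bilstm" else LSTM_UNITS


def build_model(
    variant: str,
    n_classes: int,
    input_shape: tuple[int, int, int, int] = (16, 64, 64, 3),
    dropout_rate: float = 0.4,
    seed: int = 0,
) -> ModelGraph:
    """Construct one of the three hybrid architectures.

    Trunk: Conv(16) -> Pool -> Conv(32) -> Pool -> Conv(64) -> Pool ->
    flatten -> reshape to (n_frames timesteps, features).  The head is
    selected by ``variant``; dropout follows the head, then a dense
    softmax output.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    d, h, w, c = input_shape
    div = POOL ** N_POOLS
    if d % div or h % div or w % div:
        raise ValueError(
            f"input shape {input_shape} not divisible by {div} for "
            f"{N_POOLS} poolings of size {POOL}"
        )
    timesteps = d
    flat = (d // div) * (h // div) * (w // div) * CONV_FILTERS[-1]
    if flat % timesteps:
        raise ValueError(
            f"conv output of {flat} elements cannot form {timesteps} timesteps"
        )
    features = flat // timesteps

    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    cin = c
    for li, filters in enumerate(CONV_FILTERS):
        conv = Conv3D(cin, filters, activation="relu", needs_input_grad=li > 0)
        conv.init(rng)
        layers.append(conv)
        layers.append(MaxPool3D(POOL))
        cin = filters
    layers.append(SequenceReshape(timesteps))
    if variant == "lstm":
        head: Layer = LSTM(features, LSTM_UNITS, return_sequences=False)
        head.init(rng)
        layers.append(head)
    elif variant == "stack_lstm":
        first = LSTM(features, LSTM_UNITS, return_sequences=True)
        second = LSTM(LSTM_UNITS, LSTM_UNITS, return_sequences=False)
        first.init(rng)
        second.init(rng)
        layers.extend([first, second])
    else:
        bi = Bidirectional(features, LSTM_UNITS)
        bi.init(rng)
        layers.append(bi)
    layers.append(Dropout(dropout_rate))
    head_dim = 2 * LSTM_UNITS if variant == "bilstm" else LSTM_UNITS
    dense = Dense(head_dim, n_classes)
    dense.init(rng)
    layers.append(dense)
    model = ModelGraph(
        variant=variant,
        n_classes=n_classes,
        input_shape=input_shape,
        dropout_rate=dropout_rate,
        layers=layers,
        seed=seed,
    )
    model.reset_dropout_rng(seed)
    return model


class Adam:
    """Adam optimizer over a model's layer parameters."""

    def __init__(
        self,
        model: ModelGraph,
        learning_rate: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-7,
    ) -> None:
        self.model = model
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = epsilon
        self.t = 0
        self._slots: list[tuple] = []
        for layer in model.param_layers():
            for name, p in layer.params.items():
                self._slots.append(
                    (layer, name, np.zeros_like(p), np.zeros_like(p))
                )

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer, name, m, v in self._slots:
            g = layer.grads[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            mhat = m / b1t
            vhat = v / b2t
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )
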