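"""Reference semantics of the two core layer operations.

``conv3d_forward`` evaluates a same-padded 3D convolution (the triple
sum over a (P, Q, R) kernel window across all input feature maps, plus a
per-filter bias, through the layer nonlinearity) on a single 4D feature
volume.  ``lstm_step`` advances one LSTM cell by one time step using the
standard input/forget/output gate equations on the concatenation
``[h_prev, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Conv3DLayerSpec", "LSTMCellSpec", "conv3d_forward", "lstm_step"]

_ACTIVATIONS = {
    "relu": lambda z: np.maximum(z, 0.0),
    "tanh": np.tanh,
    "linear": lambda z: z,
}


@dataclass
class Conv3DLayerSpec:
    """One same-padded 3D convolution layer.

    ``weights`` is indexed ``(p, q, r, m, j)``: kernel offsets along the
    three axes, input feature map m, output filter j.  ``bias`` is per
    filter.
    """

    n_filters: int
    kernel: tuple[int, int, int] = (3, 3, 3)
    padding: str = "same"
    activation: str = "relu"
    weights: np.ndarray | None = None
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.padding != "same":
            raise ValueError("only 'same' padding is supported")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation: {self.activation!r}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if self.weights.shape[:3] != tuple(self.kernel):
                raise ValueError("weights do not match kernel size")
            if self.weights.shape[4] != self.n_filters:
                raise ValueError("weights do not match n_filters")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=np.float64)
            if self.bias.shape != (self.n_filters,):
                raise ValueError("bias must be one value per filter")


def conv3d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3D convolution core on a batch.

    x: (N, D, H, W, Cin); w: (P, Q, R, Cin, Cout); b: (Cout,).
    Returns the pre-activation volume (N, D, H, W, Cout).
    """
    n, d, h, wd, cin = x.shape
    p, q, r, cin_w, cout = w.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} feature maps, kernel expects {cin_w}")
    pads = [(0, 0)] + [((k - 1) // 2, k // 2) for k in (p, q, r)] + [(0, 0)]
    xp = np.pad(x, pads)
    out = np.tile(b.astype(x.dtype), (n, d, h, wd, 1))
    for i in range(p):
        for j in range(q):
            for k in range(r):
                patch = xp[:, i : i + d, j : j + h, k : k + wd, :]
                out += patch @ w[i, j, k]
    return out


def conv3d_forward(volume: np.ndarray, layer: Conv3DLayerSpec) -> np.ndarray:
    """Apply one conv layer to a single 4D feature volume (D, H, W, Cin)."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 4:
        raise ValueError("input must be a 4D feature volume (D, H, W, Cin)")
    if layer.weights is None or layer.bias is None:
        raise ValueError("layer weights and bias must be set")
    z = conv3d_same(volume[None], layer.weights, layer.bias)[0]
    return _ACTIVATIONS[layer.activation](z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LSTMCellSpec:
    """One LSTM cell: four gate weight matrices over ``[h_prev, x]``.

    Each ``W_*`` has shape (units, units + input_dim) and each ``b_*``
    shape (units,).
    """

    units: int
    input_dim: int
    W_i: np.ndarray = None
    W_f: np.ndarray = None
    W_c: np.ndarray = None
    W_o: np.ndarray = None
    b_i: np.ndarray = None
    b_f: np.ndarray = None
    b_c: np.ndarray = None
    b_o: np.ndarray = None

    def __post_init__(self) -> None:
        shape_w = (self.units, self.units + self.input_dim)
        for name in ("W_i", "W_f", "W_c", "W_o"):
            v = getattr(self, name)
            v = np.zeros(shape_w) if v is None else np.asarray(v, dtype=np.float64)
            if v.shape != shape_w:
                raise ValueError(f"{name} must have shape {shape_w}, got {v.shape}")
            setattr(self, name, v)
        for name in ("b_i", "b_f", "b_c", "b_o"):
            v = getattr(self, name)
            v = np.zeros(self.units) if v is None else np.asarray(v, dtype=np.float64)
            if v.shape != (self.units,):
                raise ValueError(f"{name} must have shape ({self.units},)")
            setattr(self, name, v)


def lstm_step(
    x: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    cell: LSTMCellSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM time step: returns the new (h, c).

    i = sigmoid(W_i [h_prev, x] + b_i)
    f = sigmoid(W_f [h_prev, x] + b_f)
    c = f * c_prev + i * tanh(W_c [h_prev, x] + b_c)
    o = sigmoid(W_o [h_prev, x] + b_o)
    h = o * tanh(c)
    """
    x = np.asarray(x, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    if x.shape != (cell.input_dim,):
        raise ValueError(f"x must have shape ({cell.input_dim},), got {x.shape}")
    if h_prev.shape != (cell.units,) or c_prev.shape != (cell.units,):
        raise ValueError(f"h_prev and c_prev must have shape ({cell.units},)")
    hx = np.concatenate([h_prev, x])
    i = _sigmoid(cell.W_i @ hx + cell.b_i)
    f = _sigmoid(cell.W_f @ hx + cell.b_f)
    c = f * c_prev + i * np.tanh(cell.W_c @ hx + cell.b_c)
    o = _sigmoid(cell.W_o @ hx + cell.b_o)
    h = o * np.tanh(c)
    return h, c
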