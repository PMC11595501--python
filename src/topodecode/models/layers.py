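"""Trainable NumPy layers with explicit forward/backward passes.

Convolutions run as chunked im2col GEMMs (forward, weight gradients) and
per-offset GEMMs (input gradients) so a 1-CPU, 8-GiB machine trains the
full architecture in minutes.  All activations are float32.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = [
    "Layer",
    "Conv3D",
    "MaxPool3D",
    "SequenceReshape",
    "LSTM",
    "Bidirectional",
    "Dropout",
    "Dense",
]

# elements per im2col chunk (~128 MiB of float32)
_CHUNK_ELEMS = 2 ** 25


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer: named parameters, matching gradients, fwd/bwd."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def param_layers(self) -> list["Layer"]:
        return [self]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv3D(Layer):
    """Same-padded 3D convolution, kernel (P, Q, R), stride 1."""

    def __init__(
        self,
        in_channels: int,
        n_filters: int,
        kernel: tuple[int, int, int] = (3, 3, 3),
        activation: str = "relu",
        needs_input_grad: bool = True,
    ) -> None:
        super().__init__()
        if activation not in ("relu", "tanh", "linear"):
            raise ValueError(f"unknown activation: {activation!r}")
        self.in_channels = in_channels
        self.n_filters = n_filters
        self.kernel = tuple(kernel)
        self.activation = activation
        self.needs_input_grad = needs_input_grad
        self._x: np.ndarray | None = None
        self._out: np.ndarray | None = None

    def init(self, rng: np.random.Generator) -> None:
        p, q, r = self.kernel
        rf = p * q * r
        self.params["W"] = glorot_uniform(
            rng,
            (p, q, r, self.in_channels, self.n_filters),
            rf * self.in_channels,
            rf * self.n_filters,
        )
        self.params["b"] = np.zeros(self.n_filters, dtype=np.float32)

    def _pads(self):
        return [((k - 1) // 2, k // 2) for k in self.kernel]

    def _lowered(self, x: np.ndarray) -> np.ndarray:
        """Zero-pad and expose sliding windows along the last spatial axis.

        Returns a zero-copy view of shape (n, d+P-1, h+Q-1, w, R*Cin):
        the innermost kernel axis is merged with the channel axis, so
        the (P, Q, R, Cin, Cout) convolution becomes P*Q GEMMs with a
        contraction length of R*Cin.
        """
        from numpy.lib.stride_tricks import sliding_window_view

        c = self.in_channels
        r = self.kernel[2]
        w = x.shape[3]
        pads = [(0, 0)] + self._pads() + [(0, 0)]
        xp = np.pad(x, pads)
        flat = xp.reshape(*xp.shape[:3], xp.shape[3] * c)
        return sliding_window_view(flat, r * c, axis=3)[:, :, :, ::c, :]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 5 or x.shape[-1] != self.in_channels:
            raise ValueError(
                f"expected input (N, D, H, W, {self.in_channels}), got {x.shape}"
            )
        n, d, h, w, c = x.shape
        p, q, r = self.kernel
        wk = self.params["W"].reshape(p, q, r * c, self.n_filters)
        xl = self._lowered(x)
        z2 = None
        buf = np.empty((n, d, h, w, r * c), dtype=np.float32)
        buf2 = buf.reshape(-1, r * c)
        for i in range(p):
            for j in range(q):
                buf[...] = xl[:, i : i + d, j : j + h]
                if z2 is None:
                    z2 = buf2 @ wk[i, j]
                else:
                    z2 += buf2 @ wk[i, j]
        z2 += self.params["b"]
        out = z2.reshape(n, d, h, w, self.n_filters)
        if self.activation == "relu":
            np.maximum(out, 0.0, out=out)
        elif self.activation == "tanh":
            np.tanh(out, out=out)
        if training:
            self._x = x
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        x, out = self._x, self._out
        if x is None:
            raise RuntimeError("backward called before a training forward pass")
        n, d, h, w, c = x.shape
        p, q, r = self.kernel
        # dout is always an intermediate owned by the caller: mutate in place
        if self.activation == "relu":
            dz = np.multiply(dout, out > 0, out=dout)
        elif self.activation == "tanh":
            dz = np.multiply(dout, 1.0 - out * out, out=dout)
        else:
            dz = dout
        self.grads["b"] = dz.sum(axis=(0, 1, 2, 3))
        wk = self.params["W"].reshape(p, q, r * c, self.n_filters)
        dz2 = dz.reshape(-1, self.n_filters)
        dwk = np.zeros_like(wk)
        xl = self._lowered(x)
        buf = np.empty((n, d, h, w, r * c), dtype=np.float32)
        buf2 = buf.reshape(-1, r * c)
        dxw = None
        if self.needs_input_grad:
            # padded gradient, windows along the last spatial axis unmerged
            dxw = np.zeros(
                (n, d + p - 1, h + q - 1, w + r - 1, c), dtype=np.float32
            )
        for i in range(p):
            for j in range(q):
                buf[...] = xl[:, i : i + d, j : j + h]
                dwk[i, j] = buf2.T @ dz2
                if dxw is not None:
                    g = (dz2 @ wk[i, j].T).reshape(n, d, h, w, r, c)
                    for k in range(r):
                        dxw[:, i : i + d, j : j + h, k : k + w, :] += g[..., k, :]
        self.grads["W"] = dwk.reshape(self.params["W"].shape)
        dx = None
        if dxw is not None:
            (pl, _), (ql, _), (rl, _) = self._pads()
            dx = dxw[:, pl : pl + d, ql : ql + h, rl : rl + w, :]
        self._x = self._out = None
        return dx


class MaxPool3D(Layer):
    """Non-overlapping max pooling with pool size = stride = (2, 2, 2)."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool
        self._x: np.ndarray | None = None
        self._out: np.ndarray | None = None

    def _windows(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, c = x.shape
        p = self.pool
        return x.reshape(n, d // p, p, h // p, p, w // p, p, c)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, d, h, w, c = x.shape
        p = self.pool
        if d % p or h % p or w % p:
            raise ValueError(
                f"input {x.shape} not divisible by pool size {p} on every axis"
            )
        out = self._windows(x).max(axis=(2, 4, 6))
        if training:
            self._x = x
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # gradient routed to the maximal entries of each window; exact
        # ties (frequent at ReLU zeros) share the gradient evenly
        if self._x is None:
            raise RuntimeError("backward called before a training forward pass")
        xw = self._windows(self._x)
        ow = self._out[:, :, None, :, None, :, None, :]
        mask = xw == ow
        counts = mask.sum(axis=(2, 4, 6), dtype=np.float32)
        gw = (dout / counts)[:, :, None, :, None, :, None, :]
        dx = (mask * gw).reshape(self._x.shape)
        self._x = self._out = None
        return dx


class SequenceReshape(Layer):
    """Row-major flatten of the feature volume, reshaped to (timesteps, F)."""

    def __init__(self, timesteps: int) -> None:
        super().__init__()
        self.timesteps = timesteps
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n = x.shape[0]
        flat = int(np.prod(x.shape[1:]))
        if flat % self.timesteps:
            raise ValueError(
                f"flattened size {flat} not divisible by {self.timesteps} timesteps"
            )
        self._in_shape = x.shape
        return np.ascontiguousarray(x).reshape(n, self.timesteps, flat // self.timesteps)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class LSTM(Layer):
    """Single LSTM layer; gate order (input, forget, candidate, output).

    ``go_backwards`` processes the sequence last-to-first and is only
    supported with ``return_sequences=False`` (all that the
    bidirectional head needs).
    """

    def __init__(
        self,
        input_dim: int,
        units: int = 64,
        return_sequences: bool = False,
        go_backwards: bool = False,
    ) -> None:
        super().__init__()
        if go_backwards and return_sequences:
            raise ValueError("go_backwards with return_sequences is not supported")
        self.input_dim = input_dim
        self.units = units
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        self._cache: dict | None = None

    def init(self, rng: np.random.Generator) -> None:
        f, u = self.input_dim, self.units
        self.params["Wx"] = glorot_uniform(rng, (f, 4 * u), f, 4 * u)
        self.params["Wh"] = glorot_uniform(rng, (u, 4 * u), u, 4 * u)
        b = np.zeros(4 * u, dtype=np.float32)
        b[u : 2 * u] = 1.0  # forget-gate bias starts open
        self.params["b"] = b

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.input_dim:
            raise ValueError(
                f"expected input (N, T, {self.input_dim}), got {x.shape}"
            )
        if self.go_backwards:
            x = x[:, ::-1]
        n, t, _ = x.shape
        u = self.units
        wx, wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((n, u), dtype=np.float32)
        c = np.zeros((n, u), dtype=np.float32)
        xz = x @ wx + b  # (N, T, 4u), input contribution precomputed
        gi = np.empty((t, n, u), dtype=np.float32)
        gf = np.empty_like(gi)
        gg = np.empty_like(gi)
        go = np.empty_like(gi)
        cs = np.empty_like(gi)
        tc = np.empty_like(gi)
        hs = np.empty_like(gi)
        hp = np.empty_like(gi)
        for k in range(t):
            z = xz[:, k] + h @ wh
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            hp[k] = h
            c_prev = c
            c = f * c_prev + i * g
            th = np.tanh(c)
            h = o * th
            gi[k], gf[k], gg[k], go[k] = i, f, g, o
            cs[k], tc[k], hs[k] = c, th, h
        if training:
            self._cache = dict(x=x, gi=gi, gf=gf, gg=gg, go=go, cs=cs, tc=tc, hp=hp)
        if self.return_sequences:
            return hs.transpose(1, 0, 2)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward called before a training forward pass")
        x = cache["x"]
        n, t, _ = x.shape
        u = self.units
        wx, wh = self.params["Wx"], self.params["Wh"]
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((n, u), dtype=np.float32)
        dc_next = np.zeros((n, u), dtype=np.float32)
        if self.return_sequences:
            dout_seq = dout.transpose(1, 0, 2)
        for k in range(t - 1, -1, -1):
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dout_seq[k]
            elif k == t - 1:
                dh += dout
            i, f, g, o = cache["gi"][k], cache["gf"][k], cache["gg"][k], cache["go"][k]
            th = cache["tc"][k]
            c_prev = cache["cs"][k - 1] if k > 0 else np.zeros((n, u), dtype=np.float32)
            do = dh * th
            dc = dc_next + dh * o * (1.0 - th * th)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dwx += x[:, k].T @ dz
            dwh += cache["hp"][k].T @ dz
            db += dz.sum(axis=0)
            dx[:, k] = dz @ wx.T
            dh_next = dz @ wh.T
            dc_next = dc * f
        self.grads["Wx"] = dwx
        self.grads["Wh"] = dwh
        self.grads["b"] = db
        self._cache = None
        if self.go_backwards:
            dx = dx[:, ::-1]
        return dx


class Bidirectional(Layer):
    """Forward + backward LSTM over the same sequence, final states concatenated."""

    def __init__(self, input_dim: int, units: int = 64) -> None:
        super().__init__()
        self.units = units
        self.fw = LSTM(input_dim, units, return_sequences=False)
        self.bw = LSTM(input_dim, units, return_sequences=False, go_backwards=True)

    def param_layers(self) -> list[Layer]:
        return [self.fw, self.bw]

    def init(self, rng: np.random.Generator) -> None:
        self.fw.init(rng)
        self.bw.init(rng)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        hf = self.fw.forward(x, training)
        hb = self.bw.forward(x, training)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        u = self.units
        return self.fw.backward(dout[:, :u]) + self.bw.backward(dout[:, u:])

    def parameter_count(self) -> int:
        return self.fw.parameter_count() + self.bw.parameter_count()


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    """Fully connected layer producing logits."""

    def __init__(self, input_dim: int, units: int) -> None:
        super().__init__()
        self.input_dim = input_dim
        self.units = units
        self._x: np.ndarray | None = None

    def init(self, rng: np.random.Generator) -> None:
        self.params["W"] = glorot_uniform(
            rng, (self.input_dim, self.units), self.input_dim, self.units
        )
        self.params["b"] = np.zeros(self.units, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx
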