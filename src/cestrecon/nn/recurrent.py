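"""Recurrent layers (vanilla RNN, LSTM, GRU) with backprop through time.

Layout is (batch, time, features).  Each layer's ``forward`` returns the
full hidden sequence; ``backward`` accepts a gradient on that sequence
plus an optional extra gradient on the final hidden state (the path the
regression head uses) and returns the gradient on the input sequence.
Initial hidden (and cell) states are zero.
"""

from __future__ import annotations

import numpy as np

from .layers import Module, init_scale

__all__ = ["RNNLayer", "LSTMLayer", "GRULayer"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


class RNNLayer(Module):
    """Elman RNN: h_t = tanh(x_t Wx + h_{t-1} Wh + b)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 init_std: float, dtype=np.float32) -> None:
        super().__init__()
        self.hidden = hidden
        self._register("Wx", rng.normal(0.0, init_scale(init_std, n_in), (n_in, hidden)).astype(dtype))
        self._register("Wh", rng.normal(0.0, init_scale(init_std, hidden), (hidden, hidden)).astype(dtype))
        self._register("b", np.zeros(hidden, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        hs = np.zeros((B, T, H), dtype=x.dtype)
        h = np.zeros((B, H), dtype=x.dtype)
        xa = x @ Wx + b
        for t in range(T):
            h = np.tanh(xa[:, t] + h @ Wh)
            hs[:, t] = h
        self._x, self._hs = x, hs
        return hs

    def backward(self, dout_seq: np.ndarray, dfinal: np.ndarray | None = None) -> np.ndarray:
        x, hs = self._x, self._hs
        B, T, _ = x.shape
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dh = np.zeros((B, self.hidden), dtype=x.dtype)
        if dfinal is not None:
            dh = dh + dfinal
        dx = np.empty_like(x)
        for t in range(T - 1, -1, -1):
            dh = dh + dout_seq[:, t]
            da = dh * (1.0 - hs[:, t] ** 2)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros_like(dh)
            self.grads["Wx"] += x[:, t].T @ da
            self.grads["Wh"] += h_prev.T @ da
            self.grads["b"] += da.sum(axis=0)
            dx[:, t] = da @ Wx.T
            dh = da @ Wh.T
        return dx


class LSTMLayer(Module):
    """LSTM with gate order (input, forget, cell, output)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 init_std: float, dtype=np.float32) -> None:
        super().__init__()
        self.hidden = hidden
        self._register("Wx", rng.normal(0.0, init_scale(init_std, n_in), (n_in, 4 * hidden)).astype(dtype))
        self._register("Wh", rng.normal(0.0, init_scale(init_std, hidden), (hidden, 4 * hidden)).astype(dtype))
        self._register("b", np.zeros(4 * hidden, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        xa = x @ Wx + b
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        hs = np.zeros((B, T, H), dtype=x.dtype)
        cache = []
        for t in range(T):
            a = xa[:, t] + h @ Wh
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, tc))
        self._x, self._hs, self._cache = x, hs, cache
        return hs

    def backward(self, dout_seq: np.ndarray, dfinal: np.ndarray | None = None) -> np.ndarray:
        x, hs, cache = self._x, self._hs, self._cache
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dh = np.zeros((B, H), dtype=x.dtype)
        if dfinal is not None:
            dh = dh + dfinal
        dc = np.zeros((B, H), dtype=x.dtype)
        dx = np.empty_like(x)
        da = np.empty((B, 4 * H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc = cache[t]
            dh = dh + dout_seq[:, t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da[:, :H] = di * i * (1.0 - i)
            da[:, H : 2 * H] = df * f * (1.0 - f)
            da[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            da[:, 3 * H :] = do * o * (1.0 - o)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros_like(dh)
            self.grads["Wx"] += x[:, t].T @ da
            self.grads["Wh"] += h_prev.T @ da
            self.grads["b"] += da.sum(axis=0)
            dx[:, t] = da @ Wx.T
            dh = da @ Wh.T
            dc = dc * f
        return dx


class GRULayer(Module):
    """GRU with gate order (reset, update, candidate); separate input and
    hidden biases so the reset gate acts inside the candidate branch."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 init_std: float, dtype=np.float32) -> None:
        super().__init__()
        self.hidden = hidden
        self._register("Wx", rng.normal(0.0, init_scale(init_std, n_in), (n_in, 3 * hidden)).astype(dtype))
        self._register("Wh", rng.normal(0.0, init_scale(init_std, hidden), (hidden, 3 * hidden)).astype(dtype))
        self._register("bx", np.zeros(3 * hidden, dtype=dtype))
        self._register("bh", np.zeros(3 * hidden, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        xa = x @ Wx + self.params["bx"]
        h = np.zeros((B, H), dtype=x.dtype)
        hs = np.zeros((B, T, H), dtype=x.dtype)
        cache = []
        for t in range(T):
            ah = h @ Wh + self.params["bh"]
            r = _sigmoid(xa[:, t, :H] + ah[:, :H])
            z = _sigmoid(xa[:, t, H : 2 * H] + ah[:, H : 2 * H])
            n = np.tanh(xa[:, t, 2 * H :] + r * ah[:, 2 * H :])
            h_prev = h
            h = (1.0 - z) * n + z * h_prev
            hs[:, t] = h
            cache.append((r, z, n, ah[:, 2 * H :], h_prev))
        self._x, self._cache = x, cache
        return hs

    def backward(self, dout_seq: np.ndarray, dfinal: np.ndarray | None = None) -> np.ndarray:
        x, cache = self._x, self._cache
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dh = np.zeros((B, H), dtype=x.dtype)
        if dfinal is not None:
            dh = dh + dfinal
        dx = np.empty_like(x)
        dax = np.empty((B, 3 * H), dtype=x.dtype)
        dah = np.empty((B, 3 * H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            r, z, n, ahn, h_prev = cache[t]
            dh = dh + dout_seq[:, t]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_direct = dh * z
            dan = dn * (1.0 - n * n)
            dr = dan * ahn
            dzpre = dz * z * (1.0 - z)
            drpre = dr * r * (1.0 - r)
            dax[:, :H] = drpre
            dax[:, H : 2 * H] = dzpre
            dax[:, 2 * H :] = dan
            dah[:, :H] = drpre
            dah[:, H : 2 * H] = dzpre
            dah[:, 2 * H :] = dan * r
            self.grads["Wx"] += x[:, t].T @ dax
            self.grads["bx"] += dax.sum(axis=0)
            self.grads["Wh"] += h_prev.T @ dah
            self.grads["bh"] += dah.sum(axis=0)
            dx[:, t] = dax @ Wx.T
            dh = dh_direct + dah @ Wh.T
        return dx
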