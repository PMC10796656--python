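"""Feed-forward building blocks with explicit forward/backward passes.

Modules cache what their backward pass needs on ``forward`` and
accumulate parameter gradients into ``self.grads`` on ``backward``
(call ``zero_grad`` between optimizer steps).  They are single-use per
step, not re-entrant.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Module", "Linear", "ReLU", "Dropout", "CausalConv1d", "Conv1x1", "init_scale"]


def init_scale(init_std: float | str, fan_in: int) -> float:
    """Resolve an initialization scale.

    A float is used verbatim (constant-std recipe); the string "scaled"
    selects fan-in scaling, std = 1/sqrt(fan_in), which keeps activations
    and the weight magnitudes a trained model needs on the same order as
    the initial draw.
    """
    if init_std == "scaled":
        return float(fan_in) ** -0.5
    return float(init_std)


class Module:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def _register(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Module):
    """Affine map on the trailing axis: y = x W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_std: float, dtype=np.float32) -> None:
        super().__init__()
        self._register("W", rng.normal(0.0, init_scale(init_std, n_in), (n_in, n_out)).astype(dtype))
        self._register("b", np.zeros(n_out, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        if x.ndim == 2:
            self.grads["W"] += x.T @ dout
            self.grads["b"] += dout.sum(axis=0)
        else:  # (B, T, n_in)
            self.grads["W"] += np.tensordot(x, dout, axes=([0, 1], [0, 1]))
            self.grads["b"] += dout.sum(axis=(0, 1))
        return dout @ self.params["W"].T


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def _weightnorm_backward(v: np.ndarray, g: np.ndarray, dW: np.ndarray):
    """Chain dL/dW into (dL/dv, dL/dg) for W = g * v / ||v||_col."""
    nv = np.sqrt((v * v).sum(axis=0))
    dot = (dW * v).sum(axis=0)
    dg = dot / nv
    dv = (g / nv) * dW - (g * dot / nv**3) * v
    return dv, dg


class CausalConv1d(Module):
    """Dilated causal 1-D convolution with weight normalization.

    Input/output layout is (batch, time, channels); output at time t sees
    inputs t, t-d, ..., t-(k-1)d (zero-padded on the left).  The kernel
    is parameterized as W = g * v / ||v|| per output channel, with
    g initialized to ||v|| so the initial W equals the raw draw v.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator, init_std: float, dtype=np.float32) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.dilation = kernel, dilation
        v = rng.normal(0.0, init_scale(init_std, kernel * c_in), (kernel * c_in, c_out)).astype(dtype)
        self._register("v", v)
        self._register("g", np.sqrt((v * v).sum(axis=0)))
        self._register("b", np.zeros(c_out, dtype=dtype))

    def _weight(self) -> np.ndarray:
        v, g = self.params["v"], self.params["g"]
        return v * (g / np.sqrt((v * v).sum(axis=0)))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, C = x.shape
        k, d = self.kernel, self.dilation
        pad = (k - 1) * d
        xp = np.concatenate([np.zeros((B, pad, C), dtype=x.dtype), x], axis=1)
        # tap j = 0 is the current sample, j > 0 reach into the past
        cols = np.concatenate(
            [xp[:, pad - j * d : pad - j * d + T, :] for j in range(k)], axis=2
        )  # (B, T, k*C)
        self._cols, self._xshape = cols, x.shape
        W = self._weight()
        self._W = W
        return cols @ W + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, C = self._xshape
        k, d = self.kernel, self.dilation
        pad = (k - 1) * d
        dW = np.tensordot(self._cols, dout, axes=([0, 1], [0, 1]))
        dv, dg = _weightnorm_backward(self.params["v"], self.params["g"], dW)
        self.grads["v"] += dv
        self.grads["g"] += dg
        self.grads["b"] += dout.sum(axis=(0, 1))
        dcols = dout @ self._W.T  # (B, T, k*C)
        dxp = np.zeros((B, T + pad, C), dtype=dout.dtype)
        for j in range(k):
            dxp[:, pad - j * d : pad - j * d + T, :] += dcols[:, :, j * C : (j + 1) * C]
        return dxp[:, pad:, :]


class Conv1x1(Module):
    """Pointwise (kernel-1) convolution; used for residual downsampling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 init_std: float, dtype=np.float32) -> None:
        super().__init__()
        self._register("W", rng.normal(0.0, init_scale(init_std, c_in), (c_in, c_out)).astype(dtype))
        self._register("b", np.zeros(c_out, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += np.tensordot(self._x, dout, axes=([0, 1], [0, 1]))
        self.grads["b"] += dout.sum(axis=(0, 1))
        return dout @ self.params["W"].T
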