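"""Sequence-to-sequence regressors: sparse Z-spectrum in, dense out.

Five architectures share one interface.  The recurrent family (rnn,
lstm, gru) stacks two recurrent layers (hidden 128) with a ReLU between
them and maps the final hidden state through dropout and an affine head
to the output length.  The TCN uses four residual blocks of dilated
causal convolutions (kernel 3, dilations 1/2/4/8, 64 channels) and maps
the last time-step's features to the output.  The TCN-LSTM feeds the
TCN feature sequence into a single LSTM layer (hidden 128) whose final
state drives the head.  All weights are drawn from N(0, init_std^2);
weight-normalized kernels start at their raw draw.
"""

from __future__ import annotations

import numpy as np

from .layers import Dropout, Linear, Module, ReLU
from .recurrent import GRULayer, LSTMLayer, RNNLayer
from .tcn import TCNBlock

__all__ = ["SeqModel", "ARCHITECTURES", "interpolation_matrix"]

ARCHITECTURES = ("rnn", "lstm", "gru", "tcn", "tcn_lstm")

_CELLS = {"rnn": RNNLayer, "lstm": LSTMLayer, "gru": GRULayer}


def interpolation_matrix(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """(len(x_in), len(x_out)) matrix M with (z_in @ M) the piecewise-linear
    interpolation of samples at positions ``x_in`` onto ``x_out``.

    Positions outside the input range clamp to the nearest endpoint.  The
    matrix depends only on the two position grids, never on data.
    """
    x_in = np.asarray(x_in, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    M = np.zeros((x_in.size, x_out.size))
    j = np.clip(np.searchsorted(x_in, x_out) - 1, 0, x_in.size - 2)
    x0, x1 = x_in[j], x_in[j + 1]
    w = np.clip((x_out - x0) / (x1 - x0), 0.0, 1.0)
    M[j, np.arange(x_out.size)] = 1.0 - w
    M[j + 1, np.arange(x_out.size)] += w
    return M


class SeqModel:
    """A trainable map from (batch, input_len, channels) to (batch, output_len)."""

    def __init__(self, architecture: str, input_len: int, output_len: int,
                 n_channels: int = 1, hidden_size: int = 128, num_layers: int = 2,
                 tcn_channels: int = 64, tcn_kernel: int = 3,
                 tcn_dilations: tuple[int, ...] = (1, 2, 4, 8),
                 dropout: float = 0.2, head_mode: str = "sequence",
                 tcn_skip_input: bool = True,
                 interp_positions: tuple | None = None,
                 seed: int = 0, init_std: float | str = "scaled",
                 dtype=np.float32) -> None:
        if architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {architecture!r}; expected one of {ARCHITECTURES}"
            )
        if head_mode not in ("sequence", "final"):
            raise ValueError(f"head_mode must be 'sequence' or 'final', got {head_mode!r}")
        self.architecture = architecture
        self.input_len = input_len
        self.output_len = output_len
        self.n_channels = n_channels
        self.activation = "relu"
        self.dropout = dropout
        self.head_mode = head_mode
        self.dtype = dtype
        self.rng = np.random.default_rng(seed)
        rng, std = self.rng, init_std

        self._named: dict[str, Module] = {}
        if architecture in _CELLS:
            cell = _CELLS[architecture]
            self.rec_layers = []
            n_in = n_channels
            for i in range(num_layers):
                layer = cell(n_in, hidden_size, rng, std, dtype)
                self._named[f"rec{i}"] = layer
                self.rec_layers.append(layer)
                n_in = hidden_size
            self.inter_relus = [ReLU() for _ in range(num_layers - 1)]
            self.inter_drops = [Dropout(dropout, rng) for _ in range(num_layers - 1)]
            self.drop = None
            feat = hidden_size
        else:
            self.blocks = []
            c_in = n_channels
            for i, d in enumerate(tcn_dilations):
                blk = TCNBlock(c_in, tcn_channels, tcn_kernel, d, dropout, rng, std, dtype)
                self.blocks.append(blk)
                for j, m in enumerate(blk.submodules):
                    self._named[f"block{i}.m{j}"] = m
                c_in = tcn_channels
            if architecture == "tcn_lstm":
                self.tcn_skip_input = tcn_skip_input
                lstm_in = tcn_channels + (n_channels if tcn_skip_input else 0)
                self.lstm = LSTMLayer(lstm_in, hidden_size, rng, std, dtype)
                self._named["lstm"] = self.lstm
                self.drop = None
                feat = hidden_size
            else:
                self.lstm = None
                self.drop = None
                feat = tcn_channels
        if head_mode == "sequence":
            feat = feat * input_len
        self.head = Linear(feat, output_len, rng, std, dtype)
        # residual-branch convention: the head starts at zero so the model's
        # initial prediction is exactly the interpolation baseline below
        self.head.params["W"][...] = 0.0
        self._named["head"] = self.head

        # trainable linear bypass initialized at piecewise-linear grid
        # interpolation: the model starts at the interpolation baseline
        # and the encoder head learns the correction
        if interp_positions is None:
            interp_positions = (
                np.linspace(0.0, 1.0, input_len), np.linspace(0.0, 1.0, output_len)
            )
        self.skip = Linear(input_len, output_len, rng, std, dtype)
        self.skip.params["W"][...] = interpolation_matrix(*interp_positions).astype(dtype)
        self._named["skip"] = self.skip

    # ------------------------------------------------------------------ core
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3 or x.shape[1] != self.input_len or x.shape[2] != self.n_channels:
            raise ValueError(
                f"expected input of shape (batch, {self.input_len}, {self.n_channels}), "
                f"got {x.shape}"
            )
        B = x.shape[0]
        if self.architecture in _CELLS:
            h = x
            for i, layer in enumerate(self.rec_layers):
                h = layer.forward(h, train)
                if i < len(self.rec_layers) - 1:
                    h = self.inter_drops[i].forward(self.inter_relus[i].forward(h), train)
            if self.head_mode == "sequence":
                feats = h.reshape(B, -1)
            else:
                feats = h[:, -1, :]
            return self.head.forward(feats) + self.skip.forward(x[:, :, 0])
        h = x
        for blk in self.blocks:
            h = blk.forward(h, train)
        if self.lstm is not None:
            if self.tcn_skip_input:
                # short-range path: the raw spectrum rides along with the
                # dilated-convolution features into the LSTM
                h = np.concatenate([h, x], axis=2)
            h = self.lstm.forward(h, train)
            if self.head_mode == "sequence":
                feats = h.reshape(B, -1)
            else:
                feats = h[:, -1, :]
            return self.head.forward(feats) + self.skip.forward(x[:, :, 0])
        self._tcn_shape = h.shape
        if self.head_mode == "sequence":
            feats = h.reshape(B, -1)
        else:
            feats = h[:, -1, :]
        return self.head.forward(feats) + self.skip.forward(x[:, :, 0])

    def _head_backward_to_seq(self, dout: np.ndarray, T: int, H: int) -> np.ndarray:
        """Backprop through head (+ dropout if present) onto the (B, T, H)
        feature sequence, honoring the head mode."""
        B = dout.shape[0]
        dfeat = self.head.backward(dout)
        if self.head_mode == "sequence":
            return dfeat.reshape(B, T, H)
        d_seq = np.zeros((B, T, H), dtype=dfeat.dtype)
        d_seq[:, -1, :] = dfeat
        return d_seq

    def backward(self, dout: np.ndarray) -> None:
        self.skip.backward(dout)  # input gradient not needed
        if self.architecture in _CELLS:
            top = self.rec_layers[-1]
            d_seq = self._head_backward_to_seq(dout, self.input_len, top.hidden)
            for i in range(len(self.rec_layers) - 1, -1, -1):
                d_seq = self.rec_layers[i].backward(d_seq)
                if i > 0:
                    d_seq = self.inter_relus[i - 1].backward(
                        self.inter_drops[i - 1].backward(d_seq)
                    )
            return
        if self.lstm is not None:
            d = self._head_backward_to_seq(dout, self.input_len, self.lstm.hidden)
            d = self.lstm.backward(d)
            if self.tcn_skip_input:
                d = d[:, :, : -self.n_channels]  # drop the raw-input lanes
        else:
            T, C = self._tcn_shape[1], self._tcn_shape[2]
            d = self._head_backward_to_seq(dout, T, C)
        for blk in reversed(self.blocks):
            d = blk.backward(d)

    # ------------------------------------------------------- parameter access
    def named_modules(self) -> dict[str, Module]:
        return dict(self._named)

    def zero_grad(self) -> None:
        for m in self._named.values():
            m.zero_grad()

    def parameters(self):
        """Yield (key, param, grad) triples with stable keys."""
        for name, m in self._named.items():
            for p in sorted(m.params):
                yield f"{name}.{p}", m.params[p], m.grads[p]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {key: p.copy() for key, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {key: p for key, p, _ in self.parameters()}
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict keys do not match model: {sorted(missing)}")
        for key, p in own.items():
            arr = np.asarray(state[key], dtype=p.dtype)
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {p.shape}")
            p[...] = arr
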