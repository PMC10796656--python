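"""Residual blocks of dilated causal convolutions (the TCN unit).

Each block applies two weight-normalized causal convolutions, each
followed by ReLU and dropout, adds a residual connection (through a
pointwise convolution when the channel counts differ), and finishes
with a ReLU.
"""

from __future__ import annotations

import numpy as np

from .layers import CausalConv1d, Conv1x1, Dropout, Module, ReLU

__all__ = ["TCNBlock"]


class TCNBlock(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 dropout: float, rng: np.random.Generator, init_std: float,
                 dtype=np.float32) -> None:
        super().__init__()
        self.conv1 = CausalConv1d(c_in, c_out, kernel, dilation, rng, init_std, dtype)
        self.relu1 = ReLU()
        self.drop1 = Dropout(dropout, rng)
        self.conv2 = CausalConv1d(c_out, c_out, kernel, dilation, rng, init_std, dtype)
        self.relu2 = ReLU()
        self.drop2 = Dropout(dropout, rng)
        self.down = Conv1x1(c_in, c_out, rng, init_std, dtype) if c_in != c_out else None
        self.relu_out = ReLU()

    @property
    def submodules(self) -> list[Module]:
        mods = [self.conv1, self.conv2]
        if self.down is not None:
            mods.append(self.down)
        return mods

    def zero_grad(self) -> None:
        for m in self.submodules:
            m.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.drop1.forward(self.relu1.forward(self.conv1.forward(x, train)), train)
        y = self.drop2.forward(self.relu2.forward(self.conv2.forward(y, train)), train)
        res = x if self.down is None else self.down.forward(x, train)
        return self.relu_out.forward(y + res)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dres = d if self.down is None else self.down.backward(d)
        dy = self.conv2.backward(self.relu2.backward(self.drop2.backward(d)))
        dx = self.conv1.backward(self.relu1.backward(self.drop1.backward(dy)))
        return dx + dres
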