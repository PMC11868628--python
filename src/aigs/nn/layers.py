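"""Layer/module abstractions on top of the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .tensor import (Tensor, concat, conv2d, dropout, global_avg_pool,
                     maxpool2x2, upsample2x2)

__all__ = ["Module", "Conv2D", "Dense", "MaxPool2", "UpSample2", "Dropout",
           "ChannelAttention", "Flatten"]


class Module:
    """Base class: parameter discovery, train/eval mode, shape tracing."""

    def __init__(self):
        self.training = False

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def submodules(self):
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                yield name, attr
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, attr in vars(self).items():
            if isinstance(attr, Tensor) and attr.requires_grad:
                yield prefix + name, attr
        for name, sub in self.submodules():
            yield from sub.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, sub in self.submodules():
            sub.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state dict key mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(np.float32)


class Conv2D(Module):
    """Stride-1 'same' convolution with optional activation."""

    def __init__(self, cin: int, cout: int, k: int = 3,
                 activation: str | None = "relu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in, fan_out = k * k * cin, k * k * cout
        self.w = Tensor(_glorot(rng, (k, k, cin, cout), fan_in, fan_out),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.w, self.b)
        if self.activation == "relu":
            out = out.relu()
        elif self.activation == "sigmoid":
            out = out.sigmoid()
        return out


class Dense(Module):
    def __init__(self, fin: int, fout: int, activation: str | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(_glorot(rng, (fin, fout), fin, fout), requires_grad=True)
        self.b = Tensor(np.zeros(fout, dtype=np.float32), requires_grad=True)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        out = x.matmul(self.w) + self.b
        if self.activation == "relu":
            out = out.relu()
        elif self.activation == "sigmoid":
            out = out.sigmoid()
        elif self.activation == "softmax":
            out = out.softmax()
        return out


class MaxPool2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class UpSample2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample2x2(x)


class Dropout(Module):
    """Inverted dropout with a per-layer generator (reseedable)."""

    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        self.rate = float(rate)
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.rate, self.rng, self.training)


class ChannelAttention(Module):
    """Per-channel gate: GAP -> dense(C -> C) -> sigmoid -> scale.

    Each gate lies in (0, 1); the block recalibrates channels so the
    narrowing convolutions keep only the most informative ones.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.fc = Dense(channels, channels, activation="sigmoid", rng=rng)
        # start near-open (gate ~ 0.88) so the stacked gates do not shrink
        # activations multiplicatively at initialization
        self.fc.b.data[:] = 2.0

    def forward(self, x: Tensor) -> Tensor:
        gate = self.fc(global_avg_pool(x))          # (N, C) in (0,1)
        n, c = gate.shape
        return x * gate.reshape(n, 1, 1, c)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)
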