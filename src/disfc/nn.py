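"""Neural-network building blocks over the autodiff engine.

Every block follows the fixed internal order conv/linear -> batch-norm ->
ReLU -> dropout, with optional L2 regularization on the conv/linear weights.
All randomness (init, dropout) flows from a single `numpy.random.Generator`
supplied at construction, so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, depthwise_conv3d, pointwise_conv3d

__all__ = [
    "Module",
    "Dense",
    "BatchNorm",
    "Dropout",
    "SepConv3d",
    "SepConvBlock",
    "FCBlock",
    "ResidualGroup",
    "global_avg_pool",
    "Adam",
]


class Module:
    """Base class: parameter registry, training-mode flag, L2 bookkeeping."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._l2: list[Tensor] = []
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def add_param(self, name: str, data: np.ndarray, l2: bool = False) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self._params[name] = t
        if l2:
            self._l2.append(t)
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, t) for n, t in self._params.items()]
        for cn, child in self._children.items():
            out.extend(child.named_parameters(prefix + cn + "."))
        return out

    def l2_parameters(self) -> list[Tensor]:
        out = list(self._l2)
        for child in self._children.values():
            out.extend(child.l2_parameters())
        return out

    def parameter_count(self) -> int:
        return sum(t.data.size for t in self.parameters())

    def set_training(self, mode: bool):
        self.training = mode
        for child in self._children.values():
            child.set_training(mode)
        return self

    def zero_grad(self):
        for t in self.parameters():
            t.zero_grad()


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, l2: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = self.add_param("w", rng.normal(0.0, scale, (n_in, n_out)), l2=l2)
        self.b = self.add_param("b", np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis.

    `channel_axis=1` for (N, C, D, H, W) grids, `channel_axis=-1` for
    (N, F) feature matrices.  Running moments are used in eval mode.
    """

    def __init__(self, n_features: int, channel_axis: int = -1,
                 momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(n_features))
        self.beta = self.add_param("beta", np.zeros(n_features))
        self.channel_axis = channel_axis
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def _shaped(self, v, ndim):
        if self.channel_axis == -1:
            return v
        shape = [1] * ndim
        shape[self.channel_axis] = -1
        return v.reshape(shape) if isinstance(v, np.ndarray) else v.reshape(tuple(shape))

    def __call__(self, x: Tensor) -> Tensor:
        ndim = x.ndim
        axes = tuple(i for i in range(ndim) if i != self.channel_axis % ndim)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            shape = [1] * ndim
            shape[self.channel_axis % ndim] = -1
            mu = self.running_mean.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mu) * inv
        return xhat * self._shaped(self.gamma, ndim) + self._shaped(self.beta, ndim)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class SepConv3d(Module):
    """Separable 3-D convolution: depthwise k^3 then pointwise 1x1x1.

    Parameter count without bias is k^3*c_in + c_in*c_out versus
    k^3*c_in*c_out for a dense 3-D convolution.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, bias: bool = True, l2: bool = True):
        super().__init__()
        self.stride = stride
        self.dw = self.add_param(
            "dw", rng.normal(0.0, np.sqrt(2.0 / k**3), (c_in, k, k, k)), l2=l2
        )
        self.pw = self.add_param(
            "pw", rng.normal(0.0, np.sqrt(2.0 / c_in), (c_out, c_in)), l2=l2
        )
        self.b = self.add_param("b", np.zeros(c_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = pointwise_conv3d(depthwise_conv3d(x, self.dw, self.stride), self.pw)
        if self.b is not None:
            out = out + self.b.reshape(1, -1, 1, 1, 1)
        return out


class SepConvBlock(Module):
    """SepConv -> BN -> ReLU -> dropout."""

    def __init__(self, c_in, c_out, k, rng, stride=1, dropout=0.0):
        super().__init__()
        self.conv = SepConv3d(c_in, c_out, k, rng, stride=stride)
        self.bn = BatchNorm(c_out, channel_axis=1)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x):
        return self.drop(self.bn(self.conv(x)).relu())


class FCBlock(Module):
    """Dense -> BN -> ReLU -> dropout."""

    def __init__(self, n_in, n_out, rng, dropout=0.0):
        super().__init__()
        self.fc = Dense(n_in, n_out, rng)
        self.bn = BatchNorm(n_out)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x):
        return self.drop(self.bn(self.fc(x)).relu())


class ResidualGroup(Module):
    """A chain of SepConv blocks with one group-level shortcut connection.

    The shortcut is the identity when channel counts agree, otherwise a
    1x1x1 pointwise projection.  output = blocks(x) + shortcut(x).
    """

    def __init__(self, c_in, c_out, k, rng, n_blocks=4, dropout=0.0):
        super().__init__()
        if n_blocks < 1:
            raise ValueError("residual group needs at least one block")
        self.blocks = []
        c = c_in
        for i in range(n_blocks):
            blk = SepConvBlock(c, c_out, k, rng, dropout=dropout)
            setattr(self, f"block{i}", blk)
            self.blocks.append(blk)
            c = c_out
        self.proj = None
        if c_in != c_out:
            self.proj = self.add_param(
                "proj", rng.normal(0.0, np.sqrt(2.0 / c_in), (c_out, c_in)), l2=True
            )

    def __call__(self, x):
        h = x
        for blk in self.blocks:
            h = blk(h)
        shortcut = x if self.proj is None else pointwise_conv3d(x, Tensor._wrap(self.proj))
        return h + shortcut


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, D, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3, 4))


class Adam:
    """Adam with per-step learning rate and additive L2 gradient terms."""

    def __init__(self, params, l2_params=(), l2_strength=0.0,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.l2_ids = {id(p) for p in l2_params}
        self.l2_strength = l2_strength
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if id(p) in self.l2_ids and self.l2_strength > 0:
                g = g + 2.0 * self.l2_strength * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)
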