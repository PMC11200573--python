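"""Neural-network building blocks and the AdamW optimizer.

Thin module system over :mod:`fquwf.autograd`, patterned after the usual
layer APIs: modules own parameters and buffers, expose ``state_dict`` /
``load_state_dict``, and switch between train and eval mode (batch-norm uses
batch statistics while training and running statistics at inference).

All initialisation draws from an explicit :class:`numpy.random.Generator`,
so identical (config, seed) pairs build bit-identical networks.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential",
    "Conv2d", "ConvTranspose2d", "Linear", "BatchNorm2d",
    "LeakyReLU", "PReLU", "PixelShuffle", "AvgPool3x3",
    "AdamW",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, key, value):
        if isinstance(value, Parameter):
            self._params[key] = value
        elif isinstance(value, Module):
            self._modules[key] = value
        object.__setattr__(self, key, value)

    def register_buffer(self, key, value):
        self._buffers[key] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, key, self._buffers[key])

    def _set_buffer(self, key, value):
        self._buffers[key] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, key, self._buffers[key])

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield (prefix + k, p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield (prefix + k, b)
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, flag: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict:
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        d.update({"buffer:" + k: b.copy() for k, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict) -> None:
        params = dict(self.named_parameters())
        for k, v in d.items():
            if k.startswith("buffer:"):
                name = k[len("buffer:"):]
                owner, leaf = self._resolve(name)
                owner._set_buffer(leaf, v)
            else:
                if params[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}")
                params[k].data = v.copy()

    def _resolve(self, dotted: str):
        parts = dotted.split(".")
        owner = self
        for p in parts[:-1]:
            owner = owner._modules[p]
        return owner, parts[-1]

    def param_checksum(self) -> float:
        """Cheap fingerprint of all parameters and buffers (for freeze audits)."""
        total = 0.0
        for _, p in self.named_parameters():
            total += float(np.sum(p.data * 1.0))
            total += float(np.sum(np.abs(p.data)))
        for _, b in self.named_buffers():
            total += float(np.sum(b)) + float(np.sum(np.abs(b)))
        return total

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._list)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, *, stride=1, pad=None, dilation=1,
                 bias=True, rng: np.random.Generator):
        super().__init__()
        self.stride, self.dilation = stride, dilation
        self.pad = (dilation * (k - 1)) // 2 if pad is None else pad
        self.weight = Parameter(_he_init(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      pad=self.pad, dilation=self.dilation)


class ConvTranspose2d(Module):
    """3x3 transposed convolution that exactly doubles H and W."""

    def __init__(self, cin, cout, k=3, *, stride=2, pad=1, output_padding=1,
                 rng: np.random.Generator):
        super().__init__()
        self.stride, self.pad, self.output_padding = stride, pad, output_padding
        self.weight = Parameter(_he_init(rng, (cin, cout, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride,
                                pad=self.pad, output_padding=self.output_padding)


class Linear(Module):
    def __init__(self, cin, cout, *, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, channels, *, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.register_buffer("running_mean", np.zeros((1, channels, 1, 1)))
        self.register_buffer("running_var", np.ones((1, channels, 1, 1)))

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._set_buffer("running_mean",
                             (1 - m) * self.running_mean + m * mu.data)
            self._set_buffer("running_var",
                             (1 - m) * self.running_var + m * var.data)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * \
                ((Tensor(self.running_var) + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class PReLU(Module):
    def __init__(self, channels, init=0.25):
        super().__init__()
        self.alpha = Parameter(np.full((1, channels, 1, 1), init))

    def forward(self, x):
        pos = x.relu()
        return pos + self.alpha * (x - pos)


class PixelShuffle(Module):
    """(N, C*r^2, H, W) -> (N, C, H*r, W*r)."""

    def __init__(self, r=2):
        super().__init__()
        self.r = r

    def forward(self, x):
        N, Cr2, H, W = x.shape
        r = self.r
        C = Cr2 // (r * r)
        x = x.reshape(N, C, r, r, H, W)
        x = x.transpose((0, 1, 4, 2, 5, 3))
        return x.reshape(N, C, H * r, W * r)


class AvgPool3x3(Module):
    """3x3 mean pooling, stride 1, zero padding (channel-preserving)."""

    def forward(self, x):
        xp = x.pad2d(1)
        H, W = x.shape[-2], x.shape[-1]
        acc = None
        for di in range(3):
            for dj in range(3):
                piece = xp[..., di:di + H, dj:dj + W]
                acc = piece if acc is None else acc + piece
        return acc * (1.0 / 9.0)


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, named_params, *, lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=1e-2):
        self.params = [(n, p) for n, p in named_params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in self.params}
        self.v = {n: np.zeros_like(p.data) for n, p in self.params}

    def zero_grad(self):
        for _, p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for n, p in self.params:
            g = p.grad
            if g is None:
                continue
            self.m[n] = b1 * self.m[n] + (1 - b1) * g
            self.v[n] = b2 * self.v[n] + (1 - b2) * g * g
            mhat = self.m[n] / (1 - b1 ** self.t)
            vhat = self.v[n] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    # -- resumable state ---------------------------------------------------
    def state(self) -> dict:
        d = {"t": np.array(self.t, dtype=np.float64)}
        for n in self.m:
            d["m:" + n] = self.m[n].copy()
            d["v:" + n] = self.v[n].copy()
        return d

    def load_state(self, d: dict) -> None:
        self.t = int(d["t"])
        for n in self.m:
            self.m[n] = d["m:" + n].copy()
            self.v[n] = d["v:" + n].copy()
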