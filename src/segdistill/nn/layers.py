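"""Layer/module system: parameter registration, common layers, serialization.

Modules register :class:`Parameter` and sub-``Module`` attributes
automatically (including lists of modules) and expose
``parameters``/``state_dict``/``load_state_dict``.  Initialization is
explicitly seeded: every layer takes a ``numpy.random.Generator`` so whole
networks are reproducible from a single seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .autograd import Parameter, Tensor, conv2d

__all__ = [
    "Module",
    "ModuleList",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "Sequential",
    "ReLU",
    "parameter_checksum",
]


class Module:
    def __init__(self):
        self.training = True

    # -- registration ------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        # dedupe by identity: shared submodules contribute each tensor once
        seen: set[int] = set()
        out = []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- train state -------------------------------------------------------

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def freeze(self):
        """Disable gradient updates for all parameters."""
        for p in self.parameters():
            p.requires_grad = False
        return self

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(prefix=f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{full}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(arr, dtype=np.float32).copy()
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected key in state dict: {name}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """3x3 / 1x1 / kxk convolution, stride 1, 'same' zero padding by default."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        padding: int | None = None,
        bias: bool = True,
        groups: int = 1,
    ):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.groups = groups
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(
            _he_init(rng, (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.groups == 1:
            return conv2d(x, self.weight, self.bias, padding=self.padding)
        cpg_in = self.in_channels // self.groups
        cpg_out = self.out_channels // self.groups
        outs = []
        from .autograd import concat

        for g in range(self.groups):
            xg = x[:, g * cpg_in : (g + 1) * cpg_in, :, :]
            wg = self.weight[g * cpg_out : (g + 1) * cpg_out, :, :, :]
            bg = self.bias[g * cpg_out : (g + 1) * cpg_out] if self.bias is not None else None
            outs.append(conv2d(xg, wg, bg, padding=self.padding))
        return concat(outs, axis=1)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(in_features, out_features)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, num_features, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, num_features, 1, 1), dtype=np.float32))
        self.running_mean = np.zeros((1, num_features, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, num_features, 1, 1), dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean *= 1.0 - self.momentum
            self.running_mean += self.momentum * mu.data
            self.running_var *= 1.0 - self.momentum
            self.running_var += self.momentum * var.data
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.steps = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.steps:
            x = m(x)
        return x


def refresh_batchnorm(module: Module, forward_fn, batches, momentum: float = 0.5, passes: int = 2) -> None:
    """Re-estimate batch-norm running statistics for the current weights.

    ``forward_fn(batch)`` must run the module on one batch in training mode.
    Needed after weight averaging, which invalidates statistics accumulated
    against earlier weights.
    """
    bns = [m for m in module.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    old = [b.momentum for b in bns]
    for b in bns:
        b.momentum = momentum
    module.train()
    for _ in range(passes):
        for batch in batches:
            forward_fn(batch)
    for b, m in zip(bns, old):
        b.momentum = m
    module.eval()


def parameter_checksum(module: Module) -> str:
    """SHA-256 over all parameter bytes in registration order."""
    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()
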