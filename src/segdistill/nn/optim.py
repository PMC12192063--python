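"""SGD with momentum/weight decay and the polynomial learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter

__all__ = ["SGD", "EMA", "PolyLR"]


class SGD:
    """Stochastic gradient descent with classical momentum.

    Weight decay is applied as L2 regularization added to the gradient.
    Parameters with ``requires_grad=False`` (frozen networks) are skipped.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
        max_grad_norm: float = 0.0,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.max_grad_norm = float(max_grad_norm)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def _clip(self) -> None:
        total = 0.0
        for p in self.params:
            if p.requires_grad and p.grad is not None:
                total += float((p.grad.astype(np.float64) ** 2).sum())
        norm = np.sqrt(total)
        if norm > self.max_grad_norm:
            scale = self.max_grad_norm / (norm + 1e-12)
            for p in self.params:
                if p.requires_grad and p.grad is not None:
                    p.grad = p.grad * scale

    def step(self) -> None:
        if self.max_grad_norm > 0:
            self._clip()
        for p, v in zip(self.params, self._velocity):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class EMA:
    """Exponential moving average of parameter values over late iterates.

    Evaluating the averaged iterate rather than the last SGD step removes
    most endpoint noise at the small batch sizes this package trains with.
    Averaging only starts after ``start_step`` updates so early, fast-moving
    weights do not pollute the average; after ``copy_to`` any batch-norm
    running statistics must be re-estimated against the averaged weights.
    """

    def __init__(self, params: list[Parameter], decay: float = 0.98, start_step: int = 0):
        self.params = list(params)
        self.decay = float(decay)
        self.start_step = int(start_step)
        self._step = 0
        self._n = 0
        self.shadow = [p.data.copy() for p in self.params]

    def update(self) -> None:
        self._step += 1
        if self._step <= self.start_step:
            return
        self._n += 1
        if self._n == 1:
            for s, p in zip(self.shadow, self.params):
                s[...] = p.data
            return
        d = min(self.decay, 1.0 - 1.0 / self._n)  # warmup toward plain mean
        for s, p in zip(self.shadow, self.params):
            s *= d
            s += (1.0 - d) * p.data

    def copy_to(self) -> None:
        if self._n == 0:
            return
        for s, p in zip(self.shadow, self.params):
            p.data = s.copy()


class PolyLR:
    """lr(iter) = lr0 * (1 - iter/max_iter)^power."""

    def __init__(self, optimizer: SGD, max_iter: int, power: float = 0.9):
        self.optimizer = optimizer
        self.lr0 = optimizer.lr
        self.max_iter = max(1, int(max_iter))
        self.power = float(power)
        self._iter = 0

    def step(self) -> None:
        self._iter = min(self._iter + 1, self.max_iter)
        frac = 1.0 - self._iter / self.max_iter
        self.optimizer.lr = self.lr0 * (frac**self.power)
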