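"""Gradient optimizers: Adam, AdamW, Adadelta and Adafactor.

Each maintains per-parameter state keyed by position in the parameter list,
so a (model, optimizer) pair advanced step by step is fully deterministic.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

__all__ = ["Optimizer", "Adam", "AdamW", "Adadelta", "Adafactor", "make_optimizer", "OPTIMIZERS"]


class Optimizer:
    def __init__(self, params: list[Tensor]):
        self.params = list(params)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _update(self, i, g):
        self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
        self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
        mhat = self.m[i] / (1 - self.beta1**self.t)
        vhat = self.v[i] / (1 - self.beta2**self.t)
        return self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            p.data -= self._update(i, p.grad)


class AdamW(Adam):
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3, weight_decay: float = 1e-2, **kw):
        super().__init__(params, lr=lr, **kw)
        self.weight_decay = weight_decay

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            p.data -= self._update(i, p.grad) + self.lr * self.weight_decay * p.data


class Adadelta(Optimizer):
    def __init__(self, params, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6):
        super().__init__(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.eg2 = [np.zeros_like(p.data) for p in self.params]
        self.ed2 = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.eg2[i] = self.rho * self.eg2[i] + (1 - self.rho) * g * g
            dx = -np.sqrt(self.ed2[i] + self.eps) / np.sqrt(self.eg2[i] + self.eps) * g
            self.ed2[i] = self.rho * self.ed2[i] + (1 - self.rho) * dx * dx
            p.data += self.lr * dx


class Adafactor(Optimizer):
    """Memory-factored adaptive optimizer with relative step sizes.

    Second moments of matrix-shaped parameters are kept as row/column
    factors; the step size scales with the parameter's own RMS.
    """

    def __init__(self, params, lr: float | None = None, eps1=1e-30, eps2=1e-3, clip=1.0):
        super().__init__(params)
        self.lr, self.eps1, self.eps2, self.clip = lr, eps1, eps2, clip
        self.t = 0
        self.state: list[dict] = []
        for p in self.params:
            if p.data.ndim >= 2:
                self.state.append(
                    {
                        "row": np.zeros(p.data.shape[:-1]),
                        "col": np.zeros(p.data.shape[:-2] + p.data.shape[-1:]),
                    }
                )
            else:
                self.state.append({"v": np.zeros_like(p.data)})

    @staticmethod
    def _rms(x):
        return np.sqrt(np.mean(x * x))

    def step(self):
        self.t += 1
        beta2t = 1.0 - self.t ** (-0.8)
        for p, st in zip(self.params, self.state):
            g = p.grad
            if g is None:
                continue
            g2 = g * g + self.eps1
            if p.data.ndim >= 2:
                st["row"] = beta2t * st["row"] + (1 - beta2t) * g2.mean(axis=-1)
                st["col"] = beta2t * st["col"] + (1 - beta2t) * g2.mean(axis=-2)
                denom = st["row"].mean(axis=-1, keepdims=True)
                v = st["row"][..., :, None] * st["col"][..., None, :] / denom[..., None]
            else:
                st["v"] = beta2t * st["v"] + (1 - beta2t) * g2
                v = st["v"]
            u = g / np.sqrt(v + self.eps1)
            u /= max(1.0, self._rms(u) / self.clip)
            alpha = self.lr if self.lr is not None else max(
                self.eps2, self._rms(p.data)
            ) * min(1e-2, 1.0 / np.sqrt(self.t))
            p.data -= alpha * u


OPTIMIZERS = {"adam": Adam, "adamw": AdamW, "adadelta": Adadelta, "adafactor": Adafactor}


def make_optimizer(name: str, params, lr: float | None = None) -> Optimizer:
    """Instantiate an optimizer by its lowercase menu name."""
    key = name.lower()
    if key not in OPTIMIZERS:
        raise ConfigurationError(
            f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}"
        )
    kwargs = {}
    if lr is not None:
        kwargs["lr"] = lr
    return OPTIMIZERS[key](params, **kwargs)


from .errors import ConfigurationError  # noqa: E402  (cycle-free tail import)
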