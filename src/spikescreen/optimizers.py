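"""First-order optimizers for the spiking classifier's dense weights.

NumPy implementations of the seven update rules swept during
hyperparameter search: Adam, Adamax, plain stochastic gradient descent
(SGO), Adagrad, Adadelta, AdamW, and RMSProp. Update equations and
default constants follow the conventional (torch-style) formulations;
weight decay is coupled (added to the gradient) everywhere except AdamW,
where it is decoupled and applied directly to the weights.

Each optimizer mutates a dict of named parameter arrays in place via
``step(grads)``.
"""

from __future__ import annotations

import numpy as np

OPTIMIZER_NAMES = ("Adam", "Adamax", "SGO", "Adagrad", "Adadelta", "AdamW", "RMSProp")


class Optimizer:
    def __init__(self, params: dict[str, np.ndarray], lr: float, wd: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        if wd < 0:
            raise ValueError("weight decay must be >= 0")
        self.params = params
        self.lr = lr
        self.wd = wd
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, w in self.params.items():
            self._update(name, w, grads[name])

    def _coupled(self, w: np.ndarray, g: np.ndarray) -> np.ndarray:
        return g + self.wd * w if self.wd else g

    def _update(self, name, w, g):  # pragma: no cover - abstract
        raise NotImplementedError


class SGO(Optimizer):
    """Plain stochastic gradient descent."""

    def _update(self, name, w, g):
        w -= self.lr * self._coupled(w, g)


class Adam(Optimizer):
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def __init__(self, params, lr, wd=0.0):
        super().__init__(params, lr, wd)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def _update(self, name, w, g):
        g = self._coupled(w, g)
        m = self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
        v = self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
        mhat = m / (1 - self.beta1**self.t)
        vhat = v / (1 - self.beta2**self.t)
        w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class AdamW(Adam):
    """Adam with decoupled weight decay applied directly to the weights."""

    def _update(self, name, w, g):
        if self.wd:
            w -= self.lr * self.wd * w
        m = self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
        v = self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
        mhat = m / (1 - self.beta1**self.t)
        vhat = v / (1 - self.beta2**self.t)
        w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Optimizer):
    """Adam variant with an infinity-norm second moment."""

    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def __init__(self, params, lr, wd=0.0):
        super().__init__(params, lr, wd)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.u = {k: np.zeros_like(v) for k, v in params.items()}

    def _update(self, name, w, g):
        g = self._coupled(w, g)
        m = self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
        u = self.u[name] = np.maximum(self.beta2 * self.u[name], np.abs(g) + self.eps)
        w -= (self.lr / (1 - self.beta1**self.t)) * m / u


class Adagrad(Optimizer):
    eps = 1e-10

    def __init__(self, params, lr, wd=0.0):
        super().__init__(params, lr, wd)
        self.G = {k: np.zeros_like(v) for k, v in params.items()}

    def _update(self, name, w, g):
        g = self._coupled(w, g)
        G = self.G[name] = self.G[name] + g * g
        w -= self.lr * g / (np.sqrt(G) + self.eps)


class Adadelta(Optimizer):
    rho, eps = 0.9, 1e-6

    def __init__(self, params, lr, wd=0.0):
        super().__init__(params, lr, wd)
        self.Eg = {k: np.zeros_like(v) for k, v in params.items()}
        self.Ed = {k: np.zeros_like(v) for k, v in params.items()}

    def _update(self, name, w, g):
        g = self._coupled(w, g)
        Eg = self.Eg[name] = self.rho * self.Eg[name] + (1 - self.rho) * g * g
        delta = np.sqrt(self.Ed[name] + self.eps) / np.sqrt(Eg + self.eps) * g
        self.Ed[name] = self.rho * self.Ed[name] + (1 - self.rho) * delta * delta
        w -= self.lr * delta


class RMSProp(Optimizer):
    alpha, eps = 0.99, 1e-8

    def __init__(self, params, lr, wd=0.0):
        super().__init__(params, lr, wd)
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def _update(self, name, w, g):
        g = self._coupled(w, g)
        v = self.v[name] = self.alpha * self.v[name] + (1 - self.alpha) * g * g
        w -= self.lr * g / (np.sqrt(v) + self.eps)


_REGISTRY = {
    "Adam": Adam,
    "Adamax": Adamax,
    "SGO": SGO,
    "Adagrad": Adagrad,
    "Adadelta": Adadelta,
    "AdamW": AdamW,
    "RMSProp": RMSProp,
}


def build_optimizer(
    name: str, params: dict[str, np.ndarray], lr: float, wd: float = 0.0
) -> Optimizer:
    """Instantiate an optimizer by its survey name."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {OPTIMIZER_NAMES}"
        ) from None
    return cls(params, lr=lr, wd=wd)


def clip_grads_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    """Rescale all gradients in place so their global L2 norm is <= max_norm."""
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
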