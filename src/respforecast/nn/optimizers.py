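"""First-order optimizers for the recurrent predictors.

The menu covers the eight update rules compared in the hyperparameter search:
SGD, Adam, Adamax, Nesterov Adam (Nadam), Adagrad, Adadelta, RMSprop and
FTRL.  Each optimizer holds its own slot variables and updates a flat list of
parameter arrays in place.  Formulas follow the standard references (Kingma &
Ba for the Adam family, Zeiler for Adadelta, McMahan et al. for FTRL);
smoothing constants are the conventional defaults.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7


class Optimizer:
    name = "base"

    def __init__(self, learning_rate: float):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.lr = float(learning_rate)
        self.t = 0

    def update(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    name = "sgd"

    def update(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


class Adam(Optimizer):
    name = "adam"
    beta1, beta2 = 0.9, 0.999

    def __init__(self, learning_rate):
        super().__init__(learning_rate)
        self.m = None
        self.v = None

    def update(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + EPS)


class Adamax(Adam):
    name = "adamax"

    def update(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]  # u: infinity norm
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        for p, g, m, u in zip(params, grads, self.m, self.v):
            m += (1 - self.beta1) * (g - m)
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            p -= self.lr * m / (b1t * (u + EPS))


class Nadam(Adam):
    """Adam with Nesterov momentum (look-ahead first moment)."""

    name = "nadam"

    def update(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b1t_next = 1.0 - self.beta1 ** (self.t + 1)
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            m_bar = self.beta1 * m / b1t_next + (1 - self.beta1) * g / b1t
            p -= self.lr * m_bar / (np.sqrt(v / b2t) + EPS)


class Adagrad(Optimizer):
    name = "adagrad"

    def __init__(self, learning_rate):
        super().__init__(learning_rate)
        self.acc = None

    def update(self, params, grads):
        if self.acc is None:
            self.acc = [np.full_like(p, 0.1) for p in params]
        for p, g, a in zip(params, grads, self.acc):
            a += g * g
            p -= self.lr * g / np.sqrt(a + EPS)


class Adadelta(Optimizer):
    name = "adadelta"
    rho = 0.95

    def __init__(self, learning_rate):
        super().__init__(learning_rate)
        self.acc_g = None
        self.acc_dx = None

    def update(self, params, grads):
        if self.acc_g is None:
            self.acc_g = [np.zeros_like(p) for p in params]
            self.acc_dx = [np.zeros_like(p) for p in params]
        for p, g, ag, ax in zip(params, grads, self.acc_g, self.acc_dx):
            ag += (1 - self.rho) * (g * g - ag)
            dx = -np.sqrt(ax + EPS) / np.sqrt(ag + EPS) * g
            ax += (1 - self.rho) * (dx * dx - ax)
            p += self.lr * dx


class RMSprop(Optimizer):
    name = "rmsprop"
    rho = 0.9

    def __init__(self, learning_rate):
        super().__init__(learning_rate)
        self.acc = None

    def update(self, params, grads):
        if self.acc is None:
            self.acc = [np.zeros_like(p) for p in params]
        for p, g, a in zip(params, grads, self.acc):
            a += (1 - self.rho) * (g * g - a)
            p -= self.lr * g / (np.sqrt(a) + EPS)


class FTRL(Optimizer):
    """Follow-the-regularized-leader proximal, without L1/L2 penalties."""

    name = "ftrl"
    power = -0.5

    def __init__(self, learning_rate):
        super().__init__(learning_rate)
        self.n = None
        self.z = None

    def update(self, params, grads):
        if self.n is None:
            self.n = [np.full_like(p, 0.1) for p in params]
            self.z = [np.zeros_like(p) for p in params]
        for p, g, n, z in zip(params, grads, self.n, self.z):
            n_new = n + g * g
            sigma = (np.sqrt(n_new) - np.sqrt(n)) / self.lr
            z += g - sigma * p
            n[...] = n_new
            p[...] = -z * self.lr / np.sqrt(n)


_REGISTRY = {
    "sgd": SGD,
    "adam": Adam,
    "adamax": Adamax,
    "nadam": Nadam,
    "nesterov_adam": Nadam,
    "adagrad": Adagrad,
    "adadelta": Adadelta,
    "rmsprop": RMSprop,
    "ftrl": FTRL,
}

OPTIMIZERS = (
    "sgd",
    "adam",
    "adamax",
    "nadam",
    "adagrad",
    "adadelta",
    "rmsprop",
    "ftrl",
)


def get_optimizer(name: str, learning_rate: float) -> Optimizer:
    key = str(name).strip().lower().replace("-", "_").replace(" ", "_")
    if key not in _REGISTRY:
        raise ValueError(f"unknown optimizer {name!r}; known: {sorted(set(_REGISTRY))}")
    return _REGISTRY[key](learning_rate)
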