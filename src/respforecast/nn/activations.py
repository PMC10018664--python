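"""Elementwise activation functions and their derivatives.

Each activation is a pair ``(f, df)`` where ``df`` is expressed in terms of
the *pre*-activation input ``x`` and, where cheaper, the cached output
``y = f(x)``.  The menu mirrors the options commonly exposed by deep-learning
toolkits for recurrent regression models: Swish, Sigmoid, ReLU, SELU, ELU,
Softsign, Tanh, Softmax, Softplus, Hard Sigmoid and Linear for hidden layers;
Linear, Sigmoid, Swish and Softsign for the output layer.
"""

from __future__ import annotations

import numpy as np

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Activation:
    """An elementwise nonlinearity with forward and backward passes."""

    def __init__(self, name, fn, grad):
        self.name = name
        self._fn = fn
        self._grad = grad

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self._fn(np.asarray(x, dtype=float))

    def grad(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """d f / d x given the pre-activation ``x`` and cached output ``y``."""
        return self._grad(x, y)

    def __repr__(self):  # pragma: no cover
        return f"Activation({self.name!r})"


def _softmax(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _softmax_grad(x, y):
    raise NotImplementedError(
        "softmax has a non-elementwise Jacobian and is rejected for scalar "
        "regression outputs; it is listed only for completeness of the "
        "hidden-activation menu"
    )


_REGISTRY = {
    "linear": Activation("linear", lambda x: x, lambda x, y: np.ones_like(x)),
    "relu": Activation(
        "relu", lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(float)
    ),
    "tanh": Activation("tanh", np.tanh, lambda x, y: 1.0 - y * y),
    "sigmoid": Activation("sigmoid", _sigmoid, lambda x, y: y * (1.0 - y)),
    "softsign": Activation(
        "softsign",
        lambda x: x / (1.0 + np.abs(x)),
        lambda x, y: 1.0 / (1.0 + np.abs(x)) ** 2,
    ),
    "elu": Activation(
        "elu",
        lambda x: np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))),
        lambda x, y: np.where(x > 0, 1.0, y + 1.0),
    ),
    "selu": Activation(
        "selu",
        lambda x: _SELU_SCALE
        * np.where(x > 0, x, _SELU_ALPHA * np.expm1(np.minimum(x, 0.0))),
        lambda x, y: _SELU_SCALE
        * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0))),
    ),
    "swish": Activation(
        "swish",
        lambda x: x * _sigmoid(x),
        # d/dx x*s(x) = s(x) + x s(x)(1-s(x)) = s + y(1-s)
        lambda x, y: _sigmoid(x) + y * (1.0 - _sigmoid(x)),
    ),
    "softplus": Activation(
        "softplus",
        lambda x: np.logaddexp(0.0, x),
        lambda x, y: _sigmoid(x),
    ),
    "hard_sigmoid": Activation(
        "hard_sigmoid",
        lambda x: np.clip(0.2 * x + 0.5, 0.0, 1.0),
        lambda x, y: np.where((x > -2.5) & (x < 2.5), 0.2, 0.0),
    ),
    "softmax": Activation("softmax", _softmax, _softmax_grad),
}

_ALIASES = {"hard sigmoid": "hard_sigmoid"}

HIDDEN_ACTIVATIONS = (
    "swish",
    "sigmoid",
    "relu",
    "selu",
    "elu",
    "softsign",
    "tanh",
    "softmax",
    "softplus",
    "hard_sigmoid",
    "linear",
)
OUTPUT_ACTIVATIONS = ("linear", "sigmoid", "swish", "softsign")


def get_activation(name: str) -> Activation:
    """Look up an activation by (case-insensitive) name."""
    key = str(name).strip().lower().replace("-", "_")
    key = _ALIASES.get(key, key.replace(" ", "_"))
    if key not in _REGISTRY:
        raise ValueError(
            f"unknown activation {name!r}; known: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[key]
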