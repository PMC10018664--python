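"""Regression losses with analytic gradients.

All losses reduce over every element of the (batch, output) array and return
``(value, dvalue/dpred)``.  Huber uses delta = 1, the customary default for
signals normalized to unit range.
"""

from __future__ import annotations

import numpy as np

HUBER_DELTA = 1.0


def _mse(pred, target):
    d = pred - target
    return float(np.mean(d * d)), (2.0 / d.size) * d


def _mae(pred, target):
    d = pred - target
    return float(np.mean(np.abs(d))), np.sign(d) / d.size


def _huber(pred, target):
    d = pred - target
    a = np.abs(d)
    quad = a <= HUBER_DELTA
    val = np.where(quad, 0.5 * d * d, HUBER_DELTA * (a - 0.5 * HUBER_DELTA))
    grad = np.where(quad, d, HUBER_DELTA * np.sign(d)) / d.size
    return float(np.mean(val)), grad


def _logcosh(pred, target):
    d = pred - target
    # log cosh d = |d| + log((1+exp(-2|d|))/2), stable for large |d|
    val = np.abs(d) + np.log1p(np.exp(-2.0 * np.abs(d))) - np.log(2.0)
    return float(np.mean(val)), np.tanh(d) / d.size


_REGISTRY = {"mse": _mse, "mae": _mae, "huber": _huber, "logcosh": _logcosh}

LOSSES = tuple(_REGISTRY)


def get_loss(name: str):
    key = str(name).strip().lower().replace("-", "_").replace(" ", "_")
    key = {"log_cosh": "logcosh"}.get(key, key)
    if key not in _REGISTRY:
        raise ValueError(f"unknown loss {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[key]
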