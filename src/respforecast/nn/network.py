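"""Assembly of the seven forecasting architectures into trainable stacks.

An architecture name plus (n_layers, units, activations, multistep head,
window geometry) determines the layer stack:

* ``simple_rnn`` / ``lstm`` / ``gru`` — n_layers stacked cells, intermediate
  layers returning sequences;
* ``bi_*`` — the same stack with every encoder layer wrapped bidirectionally
  (features double per layer);
* ``cnn_lstm`` — a 1-D convolutional feature extractor (kernel 3, filters =
  units, max-pool 2) in front of n_layers LSTM layers.

Two multistep heads are supported.  The ``vector`` head projects the encoder
summary to all O outputs at once.  The ``encoder_decoder`` head repeats the
encoder summary O times, runs it through a unidirectional decoder cell of the
same family, and projects each decoder step to one output.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    CELLS,
    Bidirectional,
    Conv1D,
    Dense,
    MaxPool1D,
    RepeatVector,
)

ARCHITECTURES = (
    "simple_rnn",
    "lstm",
    "gru",
    "bi_simple_rnn",
    "bi_lstm",
    "bi_gru",
    "cnn_lstm",
)


class SequenceModel:
    """A windowed forecaster: (batch, W) in, (batch, O) out."""

    def __init__(self, architecture: str, n_layers: int, units: int,
                 hidden_activation: str, output_activation: str,
                 multistep: str, input_len: int, output_len: int,
                 seed: int = 0):
        if architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {architecture!r}; known: {ARCHITECTURES}"
            )
        if n_layers < 1 or units < 1:
            raise ValueError("n_layers and units must be >= 1")
        if multistep not in ("vector", "encoder_decoder"):
            raise ValueError("multistep must be 'vector' or 'encoder_decoder'")
        if input_len < 1 or output_len < 1:
            raise ValueError("input_len and output_len must be >= 1")
        self.architecture = architecture
        self.input_len = input_len
        self.output_len = output_len
        self.multistep = multistep
        rng = np.random.default_rng(seed)

        bidirectional = architecture.startswith("bi_")
        base = architecture.removeprefix("bi_")
        cell_cls = CELLS["lstm" if base == "cnn_lstm" else base]

        layers = []
        n_feat = 1
        if base == "cnn_lstm":
            if input_len < 3:
                raise ValueError("cnn_lstm needs an input window of >= 3 samples")
            layers.append(Conv1D(n_feat, units, 3, hidden_activation, rng))
            layers.append(MaxPool1D(2))
            n_feat = units
        for i in range(n_layers):
            last = i == n_layers - 1
            return_sequences = not last
            if bidirectional:
                layers.append(
                    Bidirectional(cell_cls, n_feat, units, hidden_activation,
                                  rng, return_sequences=return_sequences)
                )
                n_feat = 2 * units
            else:
                layers.append(
                    cell_cls(n_feat, units, hidden_activation, rng,
                             return_sequences=return_sequences)
                )
                n_feat = units

        if multistep == "vector":
            layers.append(Dense(n_feat, output_len, output_activation, rng))
        else:
            layers.append(RepeatVector(output_len))
            layers.append(
                cell_cls(n_feat, units, hidden_activation, rng,
                         return_sequences=True)
            )
            layers.append(Dense(units, 1, output_activation, rng))
        self.layers = layers

    # -- plumbing ---------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        own = self.params
        if len(own) != len(weights):
            raise ValueError("weight list does not match this model")
        for p, w in zip(own, weights):
            if p.shape != np.shape(w):
                raise ValueError("weight shapes do not match this model")
            p[...] = w

    # -- compute ----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.input_len:
            raise ValueError(
                f"expected input of shape (batch, {self.input_len}), got {x.shape}"
            )
        h = x[:, :, None]
        for layer in self.layers:
            h = layer.forward(h)
        if h.ndim == 3:  # encoder-decoder head: (B, O, 1)
            h = h[:, :, 0]
        self._out_ndim3 = self.multistep == "encoder_decoder"
        return h

    def backward(self, dout: np.ndarray) -> None:
        d = np.asarray(dout, dtype=float)
        if self._out_ndim3:
            d = d[:, :, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)
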