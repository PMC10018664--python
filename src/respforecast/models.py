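"""The seven recurrent forecasters as scikit-learn style estimators.

:class:`RecurrentForecaster` wraps the NumPy sequence-model engine in the
familiar ``fit`` / ``predict`` / ``get_params`` interface so predictors
compose with scikit-learn pipelines and model selection.  The estimator is
deliberately an *offline* predictor: after ``fit`` the weights are frozen
and ``predict`` is a pure function — no test-time adaptation, matching how a
latency-compensation model is trained once before treatment.

:func:`recommended_config` returns, per architecture, the tuned
configuration found by the grouped hyperparameter search (layers, units,
optimizer, learning rate, activations, epochs, horizon, batch size, loss,
window geometry and multistep head).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .nn import ARCHITECTURES, SequenceModel, get_loss, get_optimizer
from .windowing import SupervisedSet, WindowSpec


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters for one predictor."""

    architecture: str
    n_layers: int
    units_per_layer: int
    hidden_activation: str
    output_activation: str
    multistep: str
    window: WindowSpec

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n_layers < 1 or self.units_per_layer < 1:
            raise ValueError("n_layers and units_per_layer must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters for one training run."""

    optimizer: str
    learning_rate: float
    epochs: int
    batch_size: int
    loss: str
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# Tuned configuration per architecture from the grouped hyperparameter
# search: (layers, units, optimizer, lr, hidden act, output act, epochs,
# horizon, batch, loss).  All architectures share W=50, O=1 and the
# encoder-decoder head.
_RECOMMENDED = {
    "simple_rnn":    (2, 10, "adam", 0.001, "swish",    "linear",   500,  1, 300, "mse"),
    "lstm":          (2, 10, "adam", 0.005, "relu",     "linear",   500,  1, 250, "mse"),
    "gru":           (3, 10, "adam", 0.005, "elu",      "linear",   1000, 1, 200, "mse"),
    "bi_simple_rnn": (3, 5,  "adam", 0.001, "tanh",     "softsign", 500,  1, 300, "mae"),
    "bi_lstm":       (2, 5,  "adam", 0.005, "softsign", "linear",   500,  1, 200, "mae"),
    "bi_gru":        (3, 5,  "adam", 0.003, "softsign", "sigmoid",  1000, 1, 200, "mae"),
    "cnn_lstm":      (1, 20, "adam", 0.003, "tanh",     "swish",    500,  1, 200, "mae"),
}


def recommended_config(architecture: str, *, seed: int = 0
                       ) -> tuple[ModelSpec, TrainConfig]:
    """Return the tuned (ModelSpec, TrainConfig) for an architecture."""
    if architecture not in _RECOMMENDED:
        raise ValueError(
            f"unknown architecture {architecture!r}; known: {ARCHITECTURES}"
        )
    (layers, units, opt, lr, hidden, output, epochs, horizon, batch,
     loss) = _RECOMMENDED[architecture]
    spec = ModelSpec(
        architecture=architecture, n_layers=layers, units_per_layer=units,
        hidden_activation=hidden, output_activation=output,
        multistep="encoder_decoder",
        window=WindowSpec(input_len=50, output_len=1, horizon=horizon),
    )
    config = TrainConfig(
        optimizer=opt, learning_rate=lr, epochs=epochs, batch_size=batch,
        loss=loss, seed=seed,
    )
    return spec, config


class TrainingDivergedWarning(UserWarning):
    pass


class RecurrentForecaster(BaseEstimator, RegressorMixin):
    """Windowed respiratory-motion forecaster.

    Parameters mirror the tunable hyperparameters of the study: the
    architecture family, depth and width, hidden/output activations, the
    multistep head type, and the optimizer settings.  ``fit`` consumes
    supervised windows ``X`` of shape ``(n, W)`` with targets ``y`` of shape
    ``(n, O)`` (or ``(n,)`` for O=1) in normalized units.

    Attributes (after ``fit``)
    --------------------------
    model_ : SequenceModel
        The trained layer stack with frozen weights.
    history_ : dict
        Per-epoch ``loss`` and (when validation data was given) ``val_loss``.
    n_params_ : int
        Trainable-parameter count, a deterministic function of the spec.
    diverged_ : bool
        True when the loss became non-finite; training stops at that epoch.
    """

    def __init__(self, architecture="gru", n_layers=3, units=10,
                 hidden_activation="elu", output_activation="linear",
                 multistep="encoder_decoder", optimizer="adam",
                 learning_rate=0.005, epochs=1000, batch_size=200,
                 loss="mse", shuffle=True, random_state=0):
        self.architecture = architecture
        self.n_layers = n_layers
        self.units = units
        self.hidden_activation = hidden_activation
        self.output_activation = output_activation
        self.multistep = multistep
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.loss = loss
        self.shuffle = shuffle
        self.random_state = random_state

    @classmethod
    def from_config(cls, spec: ModelSpec, config: TrainConfig,
                    **overrides) -> "RecurrentForecaster":
        """Build an estimator from a (ModelSpec, TrainConfig) pair."""
        kwargs = dict(
            architecture=spec.architecture, n_layers=spec.n_layers,
            units=spec.units_per_layer,
            hidden_activation=spec.hidden_activation,
            output_activation=spec.output_activation,
            multistep=spec.multistep, optimizer=config.optimizer,
            learning_rate=config.learning_rate, epochs=config.epochs,
            batch_size=config.batch_size, loss=config.loss,
            random_state=config.seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    # ------------------------------------------------------------------
    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D (n_windows, W), got shape {X.shape}")
        if y is None:
            return X
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.ndim != 2 or len(y) != len(X):
            raise ValueError("y must align with X as (n_windows, O)")
        return X, y

    def fit(self, X, y, validation_data=None):
        """Train for exactly ``epochs`` epochs (no early stopping)."""
        X, y = self._validate_xy(X, y)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty supervised set")
        ss = np.random.SeedSequence(self.random_state)
        init_seed, shuffle_seed = (int(s.generate_state(1)[0] % (2**31))
                                   for s in ss.spawn(2))
        model = SequenceModel(
            self.architecture, self.n_layers, self.units,
            self.hidden_activation, self.output_activation, self.multistep,
            input_len=X.shape[1], output_len=y.shape[1], seed=init_seed,
        )
        loss_fn = get_loss(self.loss)
        opt = get_optimizer(self.optimizer, self.learning_rate)
        rng = np.random.default_rng(shuffle_seed)
        if validation_data is not None:
            Xv, yv = self._validate_xy(*validation_data)
        n = len(X)
        history: dict[str, list[float]] = {"loss": []}
        if validation_data is not None:
            history["val_loss"] = []
        self.diverged_ = False
        for _ in range(self.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            total, seen = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                pred = model.forward(X[idx])
                value, dpred = loss_fn(pred, y[idx])
                if not np.isfinite(value):
                    self.diverged_ = True
                    break
                model.zero_grad()
                model.backward(dpred)
                opt.update(model.params, model.grads)
                total += value * len(idx)
                seen += len(idx)
            if self.diverged_:
                history["loss"].append(float("nan"))
                if validation_data is not None:
                    history["val_loss"].append(float("nan"))
                break
            history["loss"].append(total / seen)
            if validation_data is not None:
                if len(Xv):
                    vpred = self._forward_batched(model, Xv)
                    vval, _ = loss_fn(vpred, yv)
                else:
                    vval = float("nan")
                history["val_loss"].append(float(vval))
        self.model_ = model
        self.history_ = history
        self.n_params_ = model.n_params
        self.input_len_ = X.shape[1]
        self.output_len_ = y.shape[1]
        return self

    @staticmethod
    def _forward_batched(model, X, chunk=2048):
        outs = [model.forward(X[i:i + chunk]) for i in range(0, len(X), chunk)]
        return np.concatenate(outs, axis=0)

    def predict(self, X):
        """Forecast O-step outputs for each input window (frozen weights)."""
        if not hasattr(self, "model_"):
            raise ValueError("RecurrentForecaster is not fitted")
        X = self._validate_xy(X)
        if X.shape[1] != self.input_len_:
            raise ValueError(
                f"X has window length {X.shape[1]}, model expects {self.input_len_}"
            )
        out = self._forward_batched(self.model_, X)
        return out[:, 0] if self.output_len_ == 1 else out

    def fit_supervised(self, train_set: SupervisedSet,
                       val_set: SupervisedSet | None = None):
        """Convenience ``fit`` from SupervisedSet containers."""
        val = None
        if val_set is not None and len(val_set):
            val = (val_set.inputs, val_set.targets)
        return self.fit(train_set.inputs, train_set.targets, validation_data=val)

    # -- persistence ----------------------------------------------------
    def save(self, directory) -> None:
        """Persist as a weights archive plus a plain-text manifest."""
        if not hasattr(self, "model_"):
            raise ValueError("cannot save an unfitted forecaster")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "params": self.get_params(),
            "input_len": self.input_len_,
            "output_len": self.output_len_,
            "n_params": self.n_params_,
            "diverged": bool(self.diverged_),
            "history": self.history_,
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n"
        )
        np.savez(
            directory / "weights.npz",
            **{f"w{i}": w for i, w in enumerate(self.model_.get_weights())},
        )

    @classmethod
    def load(cls, directory) -> "RecurrentForecaster":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        est = cls(**manifest["params"])
        est.input_len_ = manifest["input_len"]
        est.output_len_ = manifest["output_len"]
        est.n_params_ = manifest["n_params"]
        est.diverged_ = manifest["diverged"]
        est.history_ = manifest["history"]
        with np.load(directory / "weights.npz") as npz:
            weights = [npz[f"w{i}"] for i in range(len(npz.files))]
        ss = np.random.SeedSequence(est.random_state)
        init_seed = int(ss.spawn(2)[0].generate_state(1)[0] % (2**31))
        est.model_ = SequenceModel(
            est.architecture, est.n_layers, est.units,
            est.hidden_activation, est.output_activation, est.multistep,
            input_len=est.input_len_, output_len=est.output_len_,
            seed=init_seed,
        )
        est.model_.set_weights(weights)
        return est


def build_model(spec: ModelSpec, seed: int = 0) -> SequenceModel:
    """Build an untrained layer stack from a ModelSpec."""
    return SequenceModel(
        spec.architecture, spec.n_layers, spec.units_per_layer,
        spec.hidden_activation, spec.output_activation, spec.multistep,
        input_len=spec.window.input_len, output_len=spec.window.output_len,
        seed=seed,
    )


def train(spec: ModelSpec, config: TrainConfig, train_set: SupervisedSet,
          val_set: SupervisedSet | None = None) -> RecurrentForecaster:
    """Train a forecaster for a (spec, config) pair; returns the estimator."""
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if train_set.spec.input_len != spec.window.input_len:
        raise ValueError("training-set window does not match the model spec")
    est = RecurrentForecaster.from_config(spec, config)
    return est.fit_supervised(train_set, val_set)


def predict(trained: RecurrentForecaster, inputs) -> np.ndarray:
    """Pure prediction on a batch of input windows (normalized units)."""
    return trained.predict(inputs)
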