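"""Chronological splitting and sliding-window supervised-set construction.

A trace is partitioned chronologically into train/validation/test segments
(default 35% / 5% / 60%): the model sees only the earliest part of a
fraction, mirroring how a predictor is fitted before treatment and then run
with frozen weights.  Each segment is then converted to supervised pairs
with an input-sliding window: pair *i* reads ``W`` consecutive samples and
targets the ``O`` samples starting ``h`` steps after the window ends, where
the horizon ``h`` (in samples) models the system latency the predictor must
bridge.  With 0-based indexing,

    input_i  = samples[i : i + W]
    target_i = samples[i + W + h - 1 : i + W + h - 1 + O]
    n_pairs  = L - W - h - O + 2    (0 when negative)

so ``h = 1`` is one-step-ahead forecasting: the first target sample
immediately follows the input window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import BreathingSignal


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/validation/test proportions."""

    train_frac: float = 0.35
    val_frac: float = 0.05
    test_frac: float = 0.60

    def __post_init__(self):
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f < 0 for f in fracs):
            raise ValueError("split fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fracs)}")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: input length W, output length O, horizon h."""

    input_len: int = 50
    output_len: int = 1
    horizon: int = 1

    def __post_init__(self):
        if self.input_len < 1:
            raise ValueError("input_len must be >= 1")
        if self.output_len < 1:
            raise ValueError("output_len must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")

    @property
    def min_length(self) -> int:
        """Shortest sequence yielding at least one pair."""
        return self.input_len + self.horizon + self.output_len - 1


@dataclass
class SupervisedSet:
    """Ordered (input window, target window) pairs from one segment."""

    inputs: np.ndarray   # (n_pairs, W)
    targets: np.ndarray  # (n_pairs, O)
    spec: WindowSpec
    source_id: str = ""
    insufficient_length: bool = False

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets must have equal pair counts")
        if len(self.inputs) and self.inputs.shape[1] != self.spec.input_len:
            raise ValueError("input width does not match spec")
        if len(self.targets) and self.targets.shape[1] != self.spec.output_len:
            raise ValueError("target width does not match spec")

    def __len__(self) -> int:
        return len(self.inputs)

    def export(self, inputs_path, targets_path, fmt: str = "%.9g") -> None:
        """Write the pairs as two delimited-text matrices for inspection."""
        np.savetxt(inputs_path, self.inputs, fmt=fmt, delimiter=",")
        np.savetxt(targets_path, self.targets, fmt=fmt, delimiter=",")


def n_pairs(length: int, spec: WindowSpec) -> int:
    """Closed-form pair count for a sequence of the given length."""
    return max(length - spec.input_len - spec.horizon - spec.output_len + 2, 0)


def split_signal(signal: BreathingSignal, spec: SplitSpec = SplitSpec()
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition a signal into contiguous chronological segments.

    Train and validation lengths are ``floor(frac * L)``; the test segment
    takes the remainder, so the three segments concatenate back to the full
    signal.  On very short inputs a segment may come out empty, which is
    flagged with a warning rather than an error.
    """
    y = signal.samples
    L = y.size
    if L < 3:
        raise ValueError("signal too short to split (need >= 3 samples)")
    n_train = int(np.floor(spec.train_frac * L))
    n_val = int(np.floor(spec.val_frac * L))
    train, val, test = y[:n_train], y[n_train:n_train + n_val], y[n_train + n_val:]
    for name, seg in (("train", train), ("validation", val), ("test", test)):
        if seg.size == 0:
            warnings.warn(
                f"{name} segment is empty for signal of length {L} "
                f"with fractions {spec}",
                stacklevel=2,
            )
    return train, val, test


def make_supervised(samples, spec: WindowSpec, source_id: str = ""
                    ) -> SupervisedSet:
    """Build latency-shifted supervised pairs from one contiguous segment."""
    y = np.asarray(samples, dtype=float).ravel()
    count = n_pairs(y.size, spec)
    W, O, h = spec.input_len, spec.output_len, spec.horizon
    if count == 0:
        return SupervisedSet(
            inputs=np.empty((0, W)), targets=np.empty((0, O)), spec=spec,
            source_id=source_id, insufficient_length=True,
        )
    windows = np.lib.stride_tricks.sliding_window_view(y, W)
    t_start = W + h - 1
    twindows = np.lib.stride_tricks.sliding_window_view(y[t_start:], O)
    return SupervisedSet(
        inputs=windows[:count].copy(), targets=twindows[:count].copy(),
        spec=spec, source_id=source_id,
    )


def latency_to_samples(latency_ms: float, fs: float) -> int:
    """Convert a hardware latency in ms to a prediction horizon in samples.

    Rounds to the nearest sample and never returns less than 1: the
    predictor always looks at least one step ahead.
    """
    if latency_ms < 0:
        raise ValueError("latency_ms must be non-negative")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return max(int(round(latency_ms * fs / 1000.0)), 1)
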