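"""Breathing-signal file I/O and min-max normalization.

File dialect
------------
Plain CSV with comment headers::

    # fs_hz=26.0
    # signal_id=sig0001_steady
    # pattern=steady
    time_s,amp_mm
    0.000000,3.141593
    ...

Only ``fs_hz`` is required; if absent, the sampling rate is inferred from
the median timestamp spacing.  Amplitudes are serialized with 9 significant
digits so a write/read round trip is exact to well below 1e-5 mm.

Normalization
-------------
Predictors train on signals mapped affinely into [0, 1] by the min/max of a
reference segment (min-max scaling speeds convergence and puts all patients
on a common scale).  The statistics should be fitted on the *training*
segment only and reused for validation/test, so test-time values may fall
outside [0, 1]; they are extended affinely, never clipped, because clipping
would bias the millimetre-scale error metrics after the inverse transform.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import BreathingSignal, PatternKind


class SignalFormatError(ValueError):
    """Raised for malformed signal files, with row-level context."""


def write_signal(signal: BreathingSignal, path) -> None:
    """Write a breathing signal in the package CSV dialect."""
    path = Path(path)
    t = signal.times_s
    lines = [f"# fs_hz={signal.sampling_rate_hz!r}"]
    if signal.signal_id:
        lines.append(f"# signal_id={signal.signal_id}")
    if signal.pattern is not None:
        lines.append(f"# pattern={signal.pattern.value}")
    lines.append("time_s,amp_mm")
    lines.extend(
        f"{ti:.6f},{yi:.9g}" for ti, yi in zip(t, signal.samples)
    )
    path.write_text("\n".join(lines) + "\n")


def read_signal(path) -> BreathingSignal:
    """Read a breathing signal written in the package CSV dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
            continue
        body_lines.append((lineno, line))
    if not body_lines:
        raise SignalFormatError(f"{path}: no data rows")
    header_lineno, header = body_lines[0]
    if [c.strip() for c in header.split(",")] != ["time_s", "amp_mm"]:
        raise SignalFormatError(
            f"{path}:{header_lineno}: expected header 'time_s,amp_mm', got {header!r}"
        )
    try:
        df = pd.read_csv(
            _stdio.StringIO("\n".join(line for _, line in body_lines)),
            dtype=float,
        )
    except ValueError as exc:
        raise SignalFormatError(f"{path}: malformed numeric row ({exc})") from exc
    if len(df) < 2:
        raise SignalFormatError(f"{path}: fewer than 2 samples")
    t = df["time_s"].to_numpy()
    y = df["amp_mm"].to_numpy()
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~(np.isfinite(t) & np.isfinite(y)))[0])
        raise SignalFormatError(
            f"{path}: non-finite value in data row {bad + 1}"
        )
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.flatnonzero(dt <= 0)[0])
        raise SignalFormatError(
            f"{path}: non-monotone timestamps at data row {bad + 2} "
            f"(t={t[bad + 1]!r} after t={t[bad]!r})"
        )
    if "fs_hz" in meta:
        fs = float(meta["fs_hz"])
    else:
        fs = 1.0 / float(np.median(dt))
    pattern = PatternKind(meta["pattern"]) if "pattern" in meta else None
    return BreathingSignal(
        samples=y, sampling_rate_hz=fs,
        signal_id=meta.get("signal_id", path.stem), pattern=pattern,
    )


class RangeNormalizer(BaseEstimator, TransformerMixin):
    """Affine min-max scaler mapping a reference segment onto [0, 1].

    Unlike clipping scalers, values outside the fitted range are extended
    affinely (and can be detected with :meth:`out_of_range`), which keeps
    ``inverse_transform`` an exact inverse everywhere.

    Attributes
    ----------
    y_min_, y_max_ : float
        Extrema of the fitted reference segment (strictly ``y_max_ > y_min_``).
    """

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 2:
            raise ValueError("need at least 2 samples to fit a normalizer")
        self.y_min_ = float(np.min(x))
        self.y_max_ = float(np.max(x))
        if not self.y_max_ > self.y_min_:
            raise ValueError(
                "constant sequence: normalization range would be zero"
            )
        return self

    def _check_fitted(self):
        if not hasattr(self, "y_min_"):
            raise ValueError("RangeNormalizer is not fitted")

    def transform(self, X):
        self._check_fitted()
        x = np.asarray(X, dtype=float)
        return (x - self.y_min_) / (self.y_max_ - self.y_min_)

    def inverse_transform(self, X):
        self._check_fitted()
        x = np.asarray(X, dtype=float)
        return self.y_min_ + x * (self.y_max_ - self.y_min_)

    def out_of_range(self, X) -> np.ndarray:
        """Boolean mask of samples outside the fitted [y_min_, y_max_] range."""
        self._check_fitted()
        x = np.asarray(X, dtype=float)
        return (x < self.y_min_) | (x > self.y_max_)


def fit_normalizer(samples) -> RangeNormalizer:
    """Fit a 0-1 normalizer on a reference amplitude sequence (mm)."""
    return RangeNormalizer().fit(samples)


def normalize(samples, norm: RangeNormalizer):
    """Map amplitudes (mm) into normalized units; affine outside the range."""
    return norm.transform(samples)


def denormalize(samples, norm: RangeNormalizer):
    """Map normalized units back to millimetres."""
    return norm.inverse_transform(samples)
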