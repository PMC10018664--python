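"""Synthetic breathing-trace generator.

Chest-wall amplitude during free breathing is well described by a Lujan-type
profile: a baseline plus an amplitude times ``cos^{2n}`` of the respiratory
phase, which spends more time near exhale than inhale for n > 1.  Real traces
additionally show cycle-to-cycle variability of period and depth, slow
baseline drift, and sensor noise; the generator models each of these
explicitly:

    y(t) = baseline + drift * t + A_k * cos^{2n}(pi * (t - t_k) / T_k) + noise

where cycle k has its own period ``T_k`` and depth ``A_k``, drawn around the
nominal values with configurable fractional jitter.  The phase is continuous
across cycle boundaries (every boundary is an inhale peak), so jitter never
introduces kinks.  Five qualitative regimes are provided as presets: steady,
slow/deep, slow/shallow, rapid/deep and rapid/shallow breathing.

Traces are sampled at 26 Hz by default, the frame rate of optical
marker-tracking cameras used for respiratory surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

DEFAULT_FS_HZ = 26.0


class PatternKind(str, Enum):
    """The five qualitative breathing regimes."""

    STEADY = "steady"
    SLOW_DEEP = "slow_deep"
    SLOW_SHALLOW = "slow_shallow"
    RAPID_DEEP = "rapid_deep"
    RAPID_SHALLOW = "rapid_shallow"


@dataclass(frozen=True)
class PatternParams:
    """Parameters of one breathing regime.

    Attributes
    ----------
    period_s : float
        Nominal seconds per breathing cycle.
    amplitude_mm : float
        Nominal peak-to-trough excursion.
    shape_exponent : int
        The n of the cos^{2n} cycle profile; larger n flattens the
        end-exhale plateau.
    period_jitter_frac, amplitude_jitter_frac : float
        Fractional standard deviation of the per-cycle period / amplitude.
    drift_mm_per_min : float
        Linear baseline drift rate.
    noise_sd_mm : float
        Additive Gaussian sensor noise.
    baseline_mm : float
        Resting (end-exhale) offset.
    """

    period_s: float
    amplitude_mm: float
    shape_exponent: int = 2
    period_jitter_frac: float = 0.0
    amplitude_jitter_frac: float = 0.0
    drift_mm_per_min: float = 0.0
    noise_sd_mm: float = 0.0
    baseline_mm: float = 0.0

    def __post_init__(self):
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if self.amplitude_mm < 0:
            raise ValueError("amplitude_mm must be non-negative")
        if self.shape_exponent < 1:
            raise ValueError("shape_exponent must be >= 1")
        for name in ("period_jitter_frac", "amplitude_jitter_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5]")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be non-negative")


@dataclass
class BreathingSignal:
    """A sampled breathing-amplitude trace in millimetres."""

    samples: np.ndarray
    sampling_rate_hz: float
    signal_id: str = ""
    pattern: PatternKind | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a signal needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz


# Regime presets.  Periods bracket adult respiratory rates (rapid ~ 24
# breaths/min, slow ~ 6), amplitudes bracket typical thoraco-abdominal
# excursions (shallow ~ 5 mm, deep ~ 15 mm); the steady regime is
# jitter-free by definition.  Non-steady regimes carry mild cycle jitter,
# slow drift and sub-millimetre sensor noise so downstream models face
# realistic irregularity.
_PRESETS: dict[PatternKind, PatternParams] = {
    PatternKind.STEADY: PatternParams(
        period_s=4.0, amplitude_mm=10.0, shape_exponent=2,
        period_jitter_frac=0.0, amplitude_jitter_frac=0.0,
        drift_mm_per_min=0.0, noise_sd_mm=0.0, baseline_mm=0.0,
    ),
    PatternKind.SLOW_DEEP: PatternParams(
        period_s=6.0, amplitude_mm=15.0, shape_exponent=2,
        period_jitter_frac=0.08, amplitude_jitter_frac=0.10,
        drift_mm_per_min=0.3, noise_sd_mm=0.15, baseline_mm=0.0,
    ),
    PatternKind.SLOW_SHALLOW: PatternParams(
        period_s=6.0, amplitude_mm=5.0, shape_exponent=2,
        period_jitter_frac=0.08, amplitude_jitter_frac=0.10,
        drift_mm_per_min=0.2, noise_sd_mm=0.15, baseline_mm=0.0,
    ),
    PatternKind.RAPID_DEEP: PatternParams(
        period_s=2.5, amplitude_mm=15.0, shape_exponent=2,
        period_jitter_frac=0.08, amplitude_jitter_frac=0.10,
        drift_mm_per_min=0.3, noise_sd_mm=0.15, baseline_mm=0.0,
    ),
    PatternKind.RAPID_SHALLOW: PatternParams(
        period_s=2.5, amplitude_mm=5.0, shape_exponent=2,
        period_jitter_frac=0.08, amplitude_jitter_frac=0.10,
        drift_mm_per_min=0.2, noise_sd_mm=0.15, baseline_mm=0.0,
    ),
}


def pattern_presets(kind: PatternKind | str) -> PatternParams:
    """Return the documented parameter preset for a breathing regime."""
    kind = PatternKind(kind)
    return _PRESETS[kind]


def _cycle_track(params: PatternParams, duration_s: float,
                 rng: np.random.Generator):
    """Draw per-cycle (start time, period, amplitude) covering duration_s."""
    starts, periods, amps = [], [], []
    t = 0.0
    while t < duration_s:
        T = params.period_s
        A = params.amplitude_mm
        if params.period_jitter_frac > 0:
            T *= max(1.0 + params.period_jitter_frac * rng.standard_normal(), 0.2)
        if params.amplitude_jitter_frac > 0:
            A *= max(1.0 + params.amplitude_jitter_frac * rng.standard_normal(), 0.0)
        starts.append(t)
        periods.append(T)
        amps.append(A)
        t += T
    return np.array(starts), np.array(periods), np.array(amps)


def generate_breathing(params: PatternParams, duration_s: float,
                       fs: float = DEFAULT_FS_HZ, seed: int = 0,
                       signal_id: str = "",
                       pattern: PatternKind | None = None) -> BreathingSignal:
    """Generate one breathing trace.

    The cycle-jitter and sensor-noise random streams are independent child
    streams of ``seed``, so regenerating with ``noise_sd_mm = 0`` reproduces
    the identical noiseless cycle structure.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    ss = np.random.SeedSequence(seed)
    rng_cycles, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    starts, periods, amps = _cycle_track(params, duration_s, rng_cycles)
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    phase = np.pi * (t - starts[idx]) / periods[idx]
    y = (
        params.baseline_mm
        + params.drift_mm_per_min / 60.0 * t
        + amps[idx] * np.cos(phase) ** (2 * params.shape_exponent)
    )
    if params.noise_sd_mm > 0:
        y = y + params.noise_sd_mm * rng_noise.standard_normal(n)
    return BreathingSignal(
        samples=y, sampling_rate_hz=float(fs), signal_id=signal_id,
        pattern=pattern,
    )


def generate_cohort(n_signals: int,
                    mix: dict[PatternKind | str, float] | None = None,
                    duration_range_s: tuple[float, float] = (1380.0, 3600.0),
                    fs: float = DEFAULT_FS_HZ, seed: int = 0,
                    ) -> list[BreathingSignal]:
    """Generate a cohort of traces with a specified regime mixture.

    Default durations span 23-60 min, the range typical of single
    treatment-fraction recordings.  Per-regime counts follow ``mix`` up to
    largest-remainder rounding; regime assignment and per-signal seeds are
    deterministic functions of ``seed``.
    """
    if n_signals < 1:
        raise ValueError("n_signals must be >= 1")
    if mix is None:
        mix = {k: 0.2 for k in PatternKind}
    if not mix:
        raise ValueError("mix must not be empty")
    mix = {PatternKind(k): float(v) for k, v in mix.items()}
    if any(v < 0 for v in mix.values()):
        raise ValueError("mix fractions must be non-negative")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mix fractions must sum to 1, got {total}")
    lo, hi = duration_range_s
    if not 0 < lo <= hi:
        raise ValueError("duration_range_s must satisfy 0 < min <= max")

    kinds = list(mix)
    exact = np.array([mix[k] * n_signals for k in kinds])
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: n_signals - counts.sum()]:
        counts[i] += 1

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    signals = []
    i = 0
    for kind, count in zip(kinds, counts):
        for _ in range(count):
            duration = float(rng.uniform(lo, hi))
            child_seed = int(rng.integers(0, 2**31 - 1))
            signals.append(
                generate_breathing(
                    pattern_presets(kind), duration, fs=fs, seed=child_seed,
                    signal_id=f"sig{i:04d}_{kind.value}", pattern=kind,
                )
            )
            i += 1
    return signals


def presets_config_block() -> str:
    """Human-readable dump of all regime presets (for experiment manifests)."""
    lines = []
    for kind in PatternKind:
        p = pattern_presets(kind)
        lines.append(f"[{kind.value}]")
        for name, value in vars(p).items():
            lines.append(f"  {name} = {value}")
    return "\n".join(lines)
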