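"""Prediction-quality metrics: RMSE, MAE, NRMSE, F-test, box-plot statistics.

For ground truth :math:`Y_i` and predictions :math:`\\hat Y_i` over N points,

.. math::

    \\mathrm{RMSE} = \\sqrt{\\tfrac1N \\sum_i (Y_i - \\hat Y_i)^2},\\qquad
    \\mathrm{MAE}  = \\tfrac1N \\sum_i |Y_i - \\hat Y_i|,\\qquad
    \\mathrm{NRMSE} = \\frac{\\mathrm{RMSE}}{Y_\\max - Y_\\min}.

NRMSE is scale-free: dividing by the ground-truth range makes errors
comparable across patients whose breathing amplitudes differ.  The F
statistic is the two-sample variance ratio ``var(Y)/var(Yhat)`` (sample
variances, n-1 degrees of freedom each) with a two-sided p-value — a check
that the predicted series reproduces the variability of the real one.  Box
statistics use inclusive linear-interpolation quartiles, whiskers at the
most extreme non-outlier points, and the 2.7-standard-deviation outlier
rule (99.3% coverage for normal errors).

All metrics are computed in millimetres: predictions made in normalized
units are mapped back through the training normalizer first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import RangeNormalizer
from .models import RecurrentForecaster
from .windowing import SupervisedSet

ALPHA = 0.05
OUTLIER_SD = 2.7


def _check_pair(Y, Yhat):
    Y = np.asarray(Y, dtype=float).ravel()
    Yhat = np.asarray(Yhat, dtype=float).ravel()
    if Y.size != Yhat.size:
        raise ValueError(f"length mismatch: {Y.size} vs {Yhat.size}")
    if Y.size == 0:
        raise ValueError("empty sequences")
    return Y, Yhat


def rmse(Y, Yhat) -> float:
    """Root mean square error (mm)."""
    Y, Yhat = _check_pair(Y, Yhat)
    return float(np.sqrt(np.mean((Y - Yhat) ** 2)))


def mae(Y, Yhat) -> float:
    """Mean absolute error (mm)."""
    Y, Yhat = _check_pair(Y, Yhat)
    return float(np.mean(np.abs(Y - Yhat)))


def nrmse(Y, Yhat) -> float:
    """RMSE normalized by the ground-truth range (unitless)."""
    Y, Yhat = _check_pair(Y, Yhat)
    span = float(np.max(Y) - np.min(Y))
    if span <= 0:
        raise ValueError("ground truth has zero range; NRMSE undefined")
    return rmse(Y, Yhat) / span


def f_test(Y, Yhat) -> tuple[float, float]:
    """Two-sample variance-ratio F-test between truth and prediction.

    Returns ``(F, p)`` with ``F = var(Y) / var(Yhat)`` on (n-1, m-1) degrees
    of freedom and a two-sided p-value.  Identical series give F = 1, p = 1.
    """
    Y, Yhat = _check_pair(Y, Yhat)
    if Y.size < 2:
        raise ValueError("need at least 2 points for an F-test")
    v1 = float(np.var(Y, ddof=1))
    v2 = float(np.var(Yhat, ddof=1))
    if v1 <= 0 or v2 <= 0:
        raise ValueError("zero variance: F statistic undefined")
    F = v1 / v2
    dist = stats.f(Y.size - 1, Yhat.size - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return F, float(min(p, 1.0))


@dataclass(frozen=True)
class BoxStats:
    """Box-plot summary of an error sample."""

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def box_stats(errors) -> BoxStats:
    """Quartiles, non-outlier whiskers, and 2.7-SD outliers of an error sample."""
    x = np.asarray(errors, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 values for box statistics")
    q25, med, q75 = np.percentile(x, [25, 50, 75])  # inclusive linear interp
    mean = x.mean()
    sd = x.std(ddof=0)
    outlier_mask = np.abs(x - mean) > OUTLIER_SD * sd if sd > 0 else np.zeros(x.shape, bool)
    kept = x[~outlier_mask]
    return BoxStats(
        median=float(med), q25=float(q25), q75=float(q75),
        whisker_low=float(kept.min()), whisker_high=float(kept.max()),
        outliers=np.sort(x[outlier_mask]),
    )


def improvement_pct(reference_mm: float, achieved_mm: float) -> float:
    """Relative error reduction, in percent, against a reference predictor."""
    if reference_mm <= 0:
        raise ValueError("reference_mm must be positive")
    return 100.0 * (reference_mm - achieved_mm) / reference_mm


@dataclass(frozen=True)
class MetricsReport:
    """All metrics for one model on one split of one signal."""

    n: int
    rmse_mm: float
    mae_mm: float
    nrmse: float
    f_stat: float
    p_value: float
    y_min_mm: float
    y_max_mm: float

    def __post_init__(self):
        if self.rmse_mm < 0 or self.mae_mm < 0:
            raise ValueError("error metrics must be non-negative")
        # NaN marks an undefined F-test (degenerate zero-variance input)
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def compute_report(Y_mm, Yhat_mm) -> MetricsReport:
    """Assemble the full metric report from truth/prediction in mm."""
    Y, Yhat = _check_pair(Y_mm, Yhat_mm)
    try:
        F, p = f_test(Y, Yhat)
    except ValueError:
        # degenerate (constant) series: the variance ratio is undefined
        F, p = float("nan"), float("nan")
    return MetricsReport(
        n=int(Y.size), rmse_mm=rmse(Y, Yhat), mae_mm=mae(Y, Yhat),
        nrmse=nrmse(Y, Yhat), f_stat=F, p_value=p,
        y_min_mm=float(Y.min()), y_max_mm=float(Y.max()),
    )


def evaluate_split(trained: RecurrentForecaster, test_set: SupervisedSet,
                   norm: RangeNormalizer) -> MetricsReport:
    """Score a frozen predictor on one supervised split, in millimetres.

    Inputs/targets in ``test_set`` are in normalized units; predictions and
    targets are mapped back to mm through ``norm`` before any metric is
    computed.
    """
    if len(test_set) == 0:
        raise ValueError("cannot evaluate an empty supervised set")
    pred_norm = trained.predict(test_set.inputs)
    Y_mm = norm.inverse_transform(test_set.targets).ravel()
    Yhat_mm = norm.inverse_transform(np.asarray(pred_norm)).ravel()
    return compute_report(Y_mm, Yhat_mm)


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, float]:
    """Cohort summary: mean and SD of each metric across per-signal reports."""
    if not reports:
        raise ValueError("no reports to aggregate")
    out: dict[str, float] = {"n_signals": float(len(reports))}
    for name in ("rmse_mm", "mae_mm", "nrmse"):
        values = np.array([getattr(r, name) for r in reports])
        out[f"{name}_mean"] = float(values.mean())
        out[f"{name}_sd"] = float(values.std(ddof=0))
    # fraction of signals whose truth/prediction variances differ at alpha;
    # a good predictor keeps this near zero (F near 1 everywhere)
    out["frac_f_significant"] = float(
        np.mean([r.significant for r in reports])
    )
    return out
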