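"""Experiment orchestration: simulate -> split -> window -> train -> report.

The unit of work is one breathing signal: it is split chronologically,
normalized by its training segment, windowed per the model's geometry, and
each requested architecture is trained on the training windows and scored on
the train and test windows in millimetres.  Per-signal metric reports are
aggregated into a cohort table (mean +/- SD of RMSE / MAE / NRMSE per
architecture, train and test blocks) and the architectures are ranked by
cohort mean test RMSE.

Everything is deterministic given the experiment configuration and seeds;
the report carries a provenance block (config echo, config hash, seeds,
timestamps) so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import MetricsReport, aggregate_reports, evaluate_split
from .io import RangeNormalizer, read_signal, write_signal
from .models import RecurrentForecaster, recommended_config
from .nn import ARCHITECTURES
from .synthetic import BreathingSignal, generate_cohort, presets_config_block
from .windowing import SplitSpec, SupervisedSet, WindowSpec, make_supervised, split_signal


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment."""

    architectures: tuple[str, ...] = ARCHITECTURES
    seeds: tuple[int, ...] = (0,)
    # either simulate a cohort ...
    n_signals: int = 5
    duration_range_s: tuple[float, float] = (120.0, 180.0)
    fs_hz: float = 26.0
    cohort_seed: int = 0
    # ... or read signals from files
    signal_paths: tuple[str, ...] = ()
    split: SplitSpec = field(default_factory=SplitSpec)
    epochs: int | None = None      # override of each recommended epoch count
    horizon: int | None = None     # override of the recommended latency
    output_dir: str | None = None

    def __post_init__(self):
        if not self.architectures:
            raise ValueError("at least one architecture is required")
        unknown = set(self.architectures) - set(ARCHITECTURES)
        if unknown:
            raise ValueError(f"unknown architectures: {sorted(unknown)}")
        if not self.seeds:
            raise ValueError("at least one seed is required")
        for p in self.signal_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"signal file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "split" in raw:
            raw["split"] = SplitSpec(**raw["split"])
        for key in ("architectures", "seeds", "signal_paths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "duration_range_s" in raw:
            raw["duration_range_s"] = tuple(raw["duration_range_s"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split"] = dataclasses.asdict(self.split)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)  # JSON-friendly echo
        return d


def prepare_signal(signal: BreathingSignal, split: SplitSpec,
                   window: WindowSpec
                   ) -> tuple[SupervisedSet, SupervisedSet, SupervisedSet,
                              RangeNormalizer]:
    """Split, fit the 0-1 normalizer on the training segment, and window.

    The normalizer statistics come from the training segment only, so no
    information from validation or test leaks into preprocessing.
    """
    train_seg, val_seg, test_seg = split_signal(signal, split)
    norm = RangeNormalizer().fit(train_seg)
    sid = signal.signal_id
    train_set = make_supervised(norm.transform(train_seg), window, sid)
    val_set = make_supervised(norm.transform(val_seg), window, sid)
    test_set = make_supervised(norm.transform(test_seg), window, sid)
    return train_set, val_set, test_set, norm


def train_on_signal(signal: BreathingSignal, architecture: str,
                    seed: int = 0, split: SplitSpec = SplitSpec(),
                    epochs: int | None = None, horizon: int | None = None,
                    ) -> tuple[RecurrentForecaster, RangeNormalizer,
                               dict[str, MetricsReport]]:
    """Train one architecture at its recommended configuration on one signal.

    Returns the frozen estimator, the training normalizer, and metric
    reports for the train and test splits (millimetres).
    """
    spec, config = recommended_config(architecture, seed=seed)
    window = spec.window
    if horizon is not None:
        window = WindowSpec(window.input_len, window.output_len, horizon)
    train_set, val_set, test_set, norm = prepare_signal(signal, split, window)
    if len(train_set) == 0:
        raise ValueError(
            f"signal {signal.signal_id!r}: training segment too short for "
            f"window {window}"
        )
    est = RecurrentForecaster.from_config(
        spec, config, **({} if epochs is None else {"epochs": epochs})
    )
    est.fit_supervised(train_set, val_set)
    reports = {
        "train": evaluate_split(est, train_set, norm),
        "test": evaluate_split(est, test_set, norm),
    }
    return est, norm, reports


@dataclass
class ExperimentReport:
    """Aggregated results of one experiment run."""

    per_signal: pd.DataFrame    # one row per (architecture, signal, split, seed)
    cohort: pd.DataFrame        # mean +/- SD per architecture and split
    ranking: list[str]          # architectures by ascending mean test RMSE
    provenance: dict
    failures: list[dict] = field(default_factory=list)

    def table3(self) -> pd.DataFrame:
        """Pivot: rows = (split, metric), columns = architecture."""
        rows = []
        for split in ("train", "test"):
            block = self.cohort[self.cohort["split"] == split]
            for metric in ("rmse_mm", "mae_mm", "nrmse"):
                row = {"split": split, "metric": metric}
                for _, r in block.iterrows():
                    row[r["architecture"]] = (
                        f"{r[f'{metric}_mean']:.3f} ± {r[f'{metric}_sd']:.3f}"
                        if metric != "nrmse"
                        else f"{r[f'{metric}_mean']:.3f}"
                    )
                rows.append(row)
        return pd.DataFrame(rows)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_signal.to_csv(directory / "per_signal.csv", index=False)
        self.cohort.to_csv(directory / "cohort.csv", index=False)
        self.table3().to_csv(directory / "summary_table.csv", index=False)
        (directory / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str) + "\n"
        )
        if self.failures:
            (directory / "failures.json").write_text(
                json.dumps(self.failures, indent=2) + "\n"
            )


def _config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_or_simulate(config: ExperimentConfig) -> list[BreathingSignal]:
    if config.signal_paths:
        return [read_signal(p) for p in config.signal_paths]
    return generate_cohort(
        config.n_signals, duration_range_s=config.duration_range_s,
        fs=config.fs_hz, seed=config.cohort_seed,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full simulate/load -> train -> evaluate -> aggregate pipeline.

    A failure on one (signal, architecture, seed) combination is recorded
    and the experiment continues with the remaining work.
    """
    signals = load_or_simulate(config)
    rows, failures = [], []
    per_arch_split: dict[tuple[str, str], list[MetricsReport]] = {}
    for arch in config.architectures:
        for signal in signals:
            for seed in config.seeds:
                try:
                    _, _, reports = train_on_signal(
                        signal, arch, seed=seed, split=config.split,
                        epochs=config.epochs, horizon=config.horizon,
                    )
                except Exception as exc:
                    failures.append(
                        {"architecture": arch, "signal": signal.signal_id,
                         "seed": seed, "error": str(exc)}
                    )
                    continue
                for split_name, rep in reports.items():
                    rows.append(
                        {"architecture": arch, "signal": signal.signal_id,
                         "seed": seed, "split": split_name,
                         **dataclasses.asdict(rep)}
                    )
                    per_arch_split.setdefault((arch, split_name), []).append(rep)
    per_signal = pd.DataFrame(rows)
    cohort_rows = []
    for (arch, split_name), reports in sorted(per_arch_split.items()):
        cohort_rows.append(
            {"architecture": arch, "split": split_name,
             **aggregate_reports(reports)}
        )
    cohort = pd.DataFrame(cohort_rows)
    test_block = cohort[cohort["split"] == "test"] if len(cohort) else cohort
    ranking = (
        list(test_block.sort_values("rmse_mm_mean")["architecture"])
        if len(test_block) else []
    )
    provenance = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seeds": list(config.seeds),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "presets": presets_config_block(),
    }
    report = ExperimentReport(
        per_signal=per_signal, cohort=cohort, ranking=ranking,
        provenance=provenance, failures=failures,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def make_training_objective(signal: BreathingSignal, architecture: str,
                            split: SplitSpec = SplitSpec(),
                            epochs: int | None = None):
    """Build an HPO objective: seed -> train -> validation RMSE in mm.

    The window geometry (input length, horizon, output length) is part of
    the searched configuration, so splitting and windowing are redone per
    trial.  Divergent or infeasible configurations return +inf so the sweep
    records them as failed trials instead of aborting.
    """
    from .hpo import config_to_model_kwargs

    def objective(config: dict, seed: int) -> float:
        window = WindowSpec(
            input_len=config["input_len"], output_len=config["output_len"],
            horizon=config["latency"],
        )
        try:
            train_set, val_set, _, norm = prepare_signal(signal, split, window)
            if len(train_set) == 0 or len(val_set) == 0:
                return float("inf")
            kwargs = config_to_model_kwargs(config, architecture)
            if epochs is not None:
                kwargs["epochs"] = epochs
            est = RecurrentForecaster(random_state=seed, **kwargs)
            est.fit(train_set.inputs, train_set.targets)
            if est.diverged_:
                return float("inf")
            pred = norm.inverse_transform(
                np.asarray(est.predict(val_set.inputs))
            ).ravel()
            truth = norm.inverse_transform(val_set.targets).ravel()
            return float(np.sqrt(np.mean((truth - pred) ** 2)))
        except (ValueError, FloatingPointError):
            return float("inf")

    return objective


def simulate_to_dir(n_signals: int, out_dir, seed: int = 0,
                    duration_range_s=(120.0, 180.0), fs: float = 26.0
                    ) -> list[Path]:
    """Generate a cohort and write one signal file per trace plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    signals = generate_cohort(
        n_signals, duration_range_s=duration_range_s, fs=fs, seed=seed
    )
    paths = []
    for sig in signals:
        path = out_dir / f"{sig.signal_id}.csv"
        write_signal(sig, path)
        paths.append(path)
    manifest = {
        "n_signals": n_signals, "seed": seed, "fs_hz": fs,
        "duration_range_s": list(duration_range_s),
        "files": [p.name for p in paths],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out_dir / "presets.txt").write_text(presets_config_block() + "\n")
    return paths
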