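"""Train/validation splitting and the repeated-run evaluation protocol.

Splits are made at the level of whole gait cycles (never mid-cycle) so no
cycle leaks between train and validation. The repeated-run experiment trains
one seeded model per run and reports per-run MSE/MAE/R² for both splits plus
their mean and standard deviation — the numeric content of a violin plot.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import EmbeddedDataset
from .errors import SplitError, TrainingDivergenceError
from .metrics import mae, mse_metric, r_squared
from .model import EDFNN, TrainConfig, train

METRIC_KEYS = ["t_mse", "v_mse", "t_mae", "v_mae", "t_r2", "v_r2"]


def split_train_validation(
    dataset: EmbeddedDataset, fraction: float = 0.8, seed: int = 0
) -> tuple[EmbeddedDataset, EmbeddedDataset]:
    """Seeded split by whole gait cycles into (train, validation).

    ``fraction`` is the share of cycles that goes to training; both parts are
    guaranteed non-empty. Rows follow the cycle containing their anchor.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if dataset.cycle_ids is None:
        raise SplitError("dataset carries no cycle ids; cannot split by cycle")
    cycles = np.unique(dataset.cycle_ids)
    if len(cycles) < 2:
        raise SplitError(f"need at least 2 cycles to split, got {len(cycles)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cycles)
    n_train = int(np.clip(round(fraction * len(cycles)), 1, len(cycles) - 1))
    train_set = set(perm[:n_train].tolist())
    in_train = np.fromiter((c in train_set for c in dataset.cycle_ids),
                           dtype=bool, count=len(dataset.cycle_ids))
    return dataset.subset(np.flatnonzero(in_train)), dataset.subset(np.flatnonzero(~in_train))


def evaluate_model(
    model: EDFNN, dataset: EmbeddedDataset, clamp: bool = True
) -> dict[str, float]:
    """MSE, MAE and R² of a model on one embedded dataset.

    Predictions are clamped to [0, 1) by default (a gait percent cannot leave
    the cycle); pass ``clamp=False`` for the raw regression output.
    """
    pred = model.forecast(dataset.Xd) if clamp else model.forward(dataset.Xd)
    truth = dataset.Yd
    return {
        "mse": mse_metric(pred, truth),
        "mae": mae(pred, truth),
        "r2": r_squared(pred, truth),
    }


@dataclass
class MetricsReport:
    """Per-run metrics of a repeated-run experiment, with summary statistics.

    ``runs`` holds one row per successful run with columns
    t_mse/v_mse/t_mae/v_mae/t_r2/v_r2 (t = training split, v = validation
    split, all on the normalised [0,1) percent scale). ``failures`` records
    seeds whose training diverged.
    """

    name: str
    runs: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    def mean(self, key: str) -> float:
        return float(self.runs[key].mean())

    def std(self, key: str) -> float:
        return float(self.runs[key].std(ddof=1)) if len(self.runs) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        """One row: mean and std per metric, mirroring the t-/v- column layout."""
        data = {}
        for key in METRIC_KEYS:
            data[key] = [self.mean(key)]
            data[key + "_std"] = [self.std(key)]
        return pd.DataFrame(data, index=[self.name])

    def to_csv(self, runs_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.runs.to_csv(runs_path, index_label="run")
        if summary_path is not None:
            self.summary().to_csv(summary_path, index_label="dataset")


def run_single(
    dataset: EmbeddedDataset,
    seed: int,
    train_cfg: TrainConfig | None = None,
    fraction: float = 0.8,
    hidden: int = 6,
    clamp: bool = True,
) -> dict[str, float]:
    """One seeded train/evaluate pass; the seed drives split, init and batching."""
    cfg = TrainConfig(**{**(train_cfg.__dict__ if train_cfg else {}), "seed": seed})
    tr, va = split_train_validation(dataset, fraction=fraction, seed=seed)
    model = EDFNN.for_dataset(tr, hidden=hidden, seed=seed)
    train(model, tr, cfg, validation=None)
    m_tr = evaluate_model(model, tr, clamp=clamp)
    m_va = evaluate_model(model, va, clamp=clamp)
    return {
        "t_mse": m_tr["mse"], "v_mse": m_va["mse"],
        "t_mae": m_tr["mae"], "v_mae": m_va["mae"],
        "t_r2": m_tr["r2"], "v_r2": m_va["r2"],
    }


def run_experiment(
    datasets: dict[str, EmbeddedDataset],
    n_runs: int = 100,
    seeds: list[int] | None = None,
    train_cfg: TrainConfig | None = None,
    fraction: float = 0.8,
    hidden: int = 6,
    clamp: bool = True,
) -> dict[str, MetricsReport]:
    """Repeated-run evaluation over per-subject and joined datasets.

    Each named dataset is trained ``n_runs`` times with distinct seeds
    (``seeds`` overrides the default 0..n_runs−1); a diverging run is recorded
    under ``failures`` and does not abort the sweep.
    """
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) < 1:
        raise ValueError("need at least one run")
    reports: dict[str, MetricsReport] = {}
    for name, ds in datasets.items():
        rows, failures = [], []
        for seed in seeds:
            try:
                rows.append({"seed": seed, **run_single(
                    ds, seed, train_cfg=train_cfg, fraction=fraction,
                    hidden=hidden, clamp=clamp)})
            except TrainingDivergenceError as exc:
                failures.append({"seed": seed, "epoch": exc.epoch})
        runs = pd.DataFrame(rows).set_index("seed") if rows else pd.DataFrame(
            columns=METRIC_KEYS)
        reports[name] = MetricsReport(name=name, runs=runs, failures=failures)
    return reports
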