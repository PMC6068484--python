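"""Evaluation metrics on the normalised gait-percent scale.

All metrics operate on percent values in [0, 1); ``to_percent`` converts MSE
and MAE onto the percent-of-gait-cycle scale (×100) for reporting. Unlike the
training cost, the reported MSE carries no ½ factor.
"""
from __future__ import annotations

import numpy as np

from .errors import UndefinedRSquaredError


def _pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size < 1:
        raise ValueError("need at least one value")
    return pred, truth


def mse_metric(pred, truth) -> float:
    """Standard mean squared error (1/n) Σ (ŷ_i − y_i)²."""
    pred, truth = _pair(pred, truth)
    return float(np.mean((pred - truth) ** 2))


def mae(pred, truth) -> float:
    """Mean absolute error (1/n) Σ |ŷ_i − y_i|."""
    pred, truth = _pair(pred, truth)
    return float(np.mean(np.abs(pred - truth)))


def r_squared(pred, truth) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot.

    SS_tot = Σ (ȳ − y_i)², SS_res = Σ (ŷ_i − y_i)². R² = 1 means the
    prediction fully represents the ground truth; a constant truth leaves
    SS_tot = 0 and R² undefined.
    """
    pred, truth = _pair(pred, truth)
    if truth.size < 2:
        raise ValueError("need at least two values for R²")
    ss_tot = float(np.sum((truth.mean() - truth) ** 2))
    if ss_tot == 0.0:
        raise UndefinedRSquaredError("ground truth is constant; R² undefined")
    ss_res = float(np.sum((pred - truth) ** 2))
    return 1.0 - ss_res / ss_tot


def to_percent(value: float) -> float:
    """Convert a [0,1)-scale error onto the percent-of-gait-cycle scale (×100)."""
    if value < 0:
        raise ValueError("metric value must be >= 0")
    return 100.0 * value
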