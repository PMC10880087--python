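"""Regression metrics and the model-comparison harness.

Headline metric is RMSE on the raw PCF scale; absolute percentage errors
(mean and median) complement it because PCF targets span more than an order
of magnitude and relative error is what screening users care about.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datakit import Dataset

__all__ = [
    "MetricsReport",
    "rmse",
    "percentage_errors",
    "mean_pe",
    "median_pe",
    "evaluate_predictions",
    "benchmark",
    "aggregate_repeats",
    "summary_table",
]


def _check_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1 or y.size == 0:
        raise ValueError(f"need equal-length nonempty vectors, got {y.shape} vs {yhat.shape}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("metric inputs must be finite")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root of the mean squared residual."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def percentage_errors(y, yhat) -> np.ndarray:
    """PE_i = 100 * |y_i - yhat_i| / y_i.  Requires strictly positive truths
    (relative error is undefined at zero)."""
    y, yhat = _check_pair(y, yhat)
    if np.any(y <= 0):
        raise ValueError("percentage error undefined for non-positive true values")
    return 100.0 * np.abs(y - yhat) / y


def mean_pe(y, yhat) -> float:
    return float(np.mean(percentage_errors(y, yhat)))


def median_pe(y, yhat) -> float:
    # midpoint rule for even n
    return float(np.median(percentage_errors(y, yhat)))


@dataclass
class MetricsReport:
    model: str
    rmse: float
    mean_pe: float
    median_pe: float
    n: int
    residuals: pd.DataFrame  # columns: smiles, y, yhat, residual
    complete: bool = True


def evaluate_predictions(name: str, test: Dataset, yhat) -> MetricsReport:
    y = test.targets
    yhat = np.asarray(yhat, dtype=np.float64)
    return MetricsReport(
        model=name,
        rmse=rmse(y, yhat),
        mean_pe=mean_pe(y, yhat),
        median_pe=median_pe(y, yhat),
        n=len(test),
        residuals=pd.DataFrame(
            {"smiles": test.smiles, "y": y, "yhat": yhat, "residual": y - yhat}
        ),
    )


def benchmark(models: dict[str, object], test: Dataset) -> list[MetricsReport]:
    """Score every model on the same test set, ranked by RMSE ascending
    (ties by median PE).

    `models` maps a display name to anything with a `predict(smiles) -> float`
    method.  A model failing on any molecule is flagged incomplete and ranked
    last; the others are unaffected.
    """
    reports: list[MetricsReport] = []
    for name, model in models.items():
        yhat, ok = [], True
        for smi in test.smiles:
            try:
                yhat.append(float(model.predict(smi)))
            except Exception:
                yhat.append(np.nan)
                ok = False
        if ok:
            report = evaluate_predictions(name, test, yhat)
        else:
            report = MetricsReport(name, np.inf, np.inf, np.inf, len(test),
                                   pd.DataFrame({"smiles": test.smiles, "yhat": yhat}),
                                   complete=False)
        reports.append(report)
    reports.sort(key=lambda r: (r.rmse, r.median_pe))
    return reports


def aggregate_repeats(reports: list[MetricsReport]) -> pd.DataFrame:
    """Mean +/- sd of each metric over repeated splits of one model family."""
    df = pd.DataFrame(
        {
            "model": [r.model for r in reports],
            "rmse": [r.rmse for r in reports],
            "mean_pe": [r.mean_pe for r in reports],
            "median_pe": [r.median_pe for r in reports],
        }
    )
    return df.groupby("model").agg(["mean", "std"])


def summary_table(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [r.model for r in reports],
            "rmse": [r.rmse for r in reports],
            "mean_pe": [r.mean_pe for r in reports],
            "median_pe": [r.median_pe for r in reports],
            "n": [r.n for r in reports],
            "complete": [r.complete for r in reports],
        }
    )
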