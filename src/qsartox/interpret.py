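"""Model interpretation: leave-one-descriptor-out ablation and one-at-a-time
sensitivity analysis.

Ablation retrains the model once per left-out descriptor with the full
model's hyperparameters (no per-subset re-tuning) and reports training
RMSE/R^2 and test RMSE/Q^2 per row, so the cost of dropping each descriptor
is directly comparable.

The sensitivity sweep probes one descriptor over its observed range while
holding every other descriptor at its training mean (or median), reading the
trained model's response curve; a Spearman rank correlation of probe values
against predictions summarizes the trend direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import q_squared, r_squared, rmse
from .svr import SchemaError
from .table import DescriptorTable


@dataclass
class SaCurve:
    """One-at-a-time sensitivity curve for a single descriptor."""

    descriptor: str
    grid: np.ndarray
    predictions: np.ndarray
    baseline: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("probe grid must be strictly increasing")
        if not np.all(np.isfinite(self.predictions)):
            raise ValueError("non-finite prediction on the probe grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.descriptor: self.grid, "prediction": self.predictions}
        )


@dataclass
class AblationReport:
    """Per-subset metric rows; first row is the full descriptor set."""

    rows: pd.DataFrame

    def to_csv(self, path_or_buf) -> None:
        self.rows.to_csv(path_or_buf, index=False)


def ablate(
    table_train: DescriptorTable,
    table_test: DescriptorTable,
    features: list[str],
    spec,
) -> AblationReport:
    """Train full and each leave-one-out model; report metrics per row.

    ``spec`` follows the fit/predict protocol and carries the (fixed)
    hyperparameters; every subset is trained under identical settings.
    """
    if len(features) < 2:
        raise ValueError("ablation needs at least two descriptors")
    y_tr = table_train.target()
    y_te = table_test.target()

    def one(subset: list[str], label: str) -> dict:
        model = spec.fit(table_train.X[subset], y_tr)
        p_tr = np.asarray(model.predict(table_train.X[subset]), dtype=float)
        p_te = np.asarray(model.predict(table_test.X[subset]), dtype=float)
        return {
            "excluded": label,
            "descriptors": ", ".join(subset),
            "train_rmse": rmse(p_tr, y_tr),
            "train_r2": r_squared(p_tr, y_tr),
            "test_rmse": rmse(p_te, y_te),
            "test_q2": q_squared(p_te, y_te),
        }

    rows = [one(list(features), "(none)")]
    for left_out in features:
        subset = [f for f in features if f != left_out]
        rows.append(one(subset, left_out))
    return AblationReport(rows=pd.DataFrame(rows))


def sensitivity_sweep(
    model,
    table: DescriptorTable,
    descriptor: str,
    grid_size: int = 50,
    baseline: str = "mean",
) -> SaCurve:
    """Sweep ``descriptor`` over [min, max] of the table with co-variates
    fixed at their training mean (or median)."""
    names = list(model.feature_names)
    if descriptor not in names:
        raise SchemaError(f"descriptor {descriptor!r} not in model schema")
    if grid_size < 3:
        raise ValueError("grid needs at least 3 points")
    if baseline not in ("mean", "median"):
        raise ValueError("baseline must be 'mean' or 'median'")
    X = table.X[names]
    stat = X.mean() if baseline == "mean" else X.median()
    col = X[descriptor].to_numpy(dtype=float)
    lo, hi = float(col.min()), float(col.max())
    if lo == hi:
        raise ValueError(f"descriptor {descriptor!r} is constant in the table")
    grid = np.linspace(lo, hi, grid_size)
    probe = pd.DataFrame(
        np.tile(stat.to_numpy(dtype=float), (grid_size, 1)), columns=names
    )
    probe[descriptor] = grid
    preds = np.asarray(model.predict(probe), dtype=float)
    return SaCurve(
        descriptor=descriptor,
        grid=grid,
        predictions=preds,
        baseline={k: float(v) for k, v in stat.items()},
    )


def trend_statistic(curve: SaCurve) -> float:
    """Spearman rank correlation of probe values vs. predictions in [-1, 1];
    a constant curve returns 0 by convention."""
    if len(curve.grid) < 3:
        raise ValueError("trend needs at least 3 grid points")
    if np.allclose(curve.predictions, curve.predictions[0]):
        return 0.0
    rho = stats.spearmanr(curve.grid, curve.predictions).statistic
    return float(rho)
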