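"""Validation metrics, fold construction and (C, epsilon) grid search.

RMSE = sqrt(sum (p_i - e_i)^2 / n) over predictions p and measurements e;
R^2 = 1 - SS_res/SS_tot on the training partition; Q^2 applies the same
formula to an external test partition.  By default the centring mean in Q^2
is the mean of the evaluated (test) observations; the training-mean
convention is available via ``mean_obs``.

Cross-validation refits the feature scaling inside each training fold, so no
information from held-out rows leaks into the model.  The per-grid-point
score is the pooled RMSE over all held-out residuals, which equals plain
RMSE on the union of the folds; the mean of per-fold RMSEs is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import DescriptorTable


class MetricError(ValueError):
    """Invalid metric input (length mismatch, empty, constant denominator)."""


class FoldError(ValueError):
    """Invalid cross-validation plan parameters."""


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------


def _check_pair(pred, obs, min_len=1):
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.ndim != 1 or obs.ndim != 1:
        raise MetricError("pred and obs must be 1-D vectors")
    if len(pred) != len(obs):
        raise MetricError(f"length mismatch: {len(pred)} vs {len(obs)}")
    if len(pred) < min_len:
        raise MetricError(f"need at least {min_len} samples")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(obs))):
        raise MetricError("non-finite values")
    return pred, obs


def rmse(pred, obs) -> float:
    """Root-mean-square error between predictions and observations."""
    pred, obs = _check_pair(pred, obs, min_len=1)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def r_squared(pred, obs, mean_obs: float | None = None) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    ``mean_obs`` overrides the centring mean (used by the training-mean
    convention of :func:`q_squared`); by default the mean of ``obs``.
    """
    pred, obs = _check_pair(pred, obs, min_len=2)
    e_bar = float(np.mean(obs)) if mean_obs is None else float(mean_obs)
    ss_tot = float(np.sum((obs - e_bar) ** 2))
    if ss_tot == 0.0:
        raise MetricError("constant observations: R^2 denominator is zero")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def q_squared(pred, obs_test, train_mean: float | None = None) -> float:
    """External predictivity on a held-out set.

    Same formula as :func:`r_squared` applied to the test samples.  The
    centring mean defaults to the test-set mean (the formula read literally);
    pass ``train_mean`` to use the training-mean convention instead.
    """
    return r_squared(pred, obs_test, mean_obs=train_mean)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CvPlan:
    """Deterministic k-fold assignment of n samples.

    ``assignment[i]`` is the fold label (0..k-1) of sample i; fold sizes
    differ by at most one.
    """

    k: int
    seed: int
    assignment: np.ndarray

    def __post_init__(self) -> None:
        counts = np.bincount(self.assignment, minlength=self.k)
        if len(counts) != self.k or counts.min() < 1:
            raise FoldError("assignment does not cover all folds")
        if counts.max() - counts.min() > 1:
            raise FoldError("fold sizes differ by more than one")

    @property
    def n(self) -> int:
        return len(self.assignment)

    def folds(self):
        """Yield (train_index, test_index) pairs per fold."""
        idx = np.arange(self.n)
        for f in range(self.k):
            mask = self.assignment == f
            yield idx[~mask], idx[mask]


def make_folds(n: int, k: int, seed: int) -> CvPlan:
    """Random balanced k-fold plan, deterministic given seed."""
    if k < 2:
        raise FoldError("need at least 2 folds")
    if k > n:
        raise FoldError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    # cycle fold labels over a random permutation: sizes differ by <= 1
    assignment[perm] = np.arange(n) % k
    return CvPlan(k=k, seed=seed, assignment=assignment)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CvResult:
    """Per-fold and pooled cross-validation error."""

    fold_rmse: list[float]
    pooled_rmse: float  # RMSE over the union of held-out residuals
    mean_fold_rmse: float
    predictions: np.ndarray  # out-of-fold prediction per sample


def cross_validate(
    table: DescriptorTable,
    features: list[str],
    spec,
    plan: CvPlan,
) -> CvResult:
    """k-fold cross-validation of a model spec on the named features.

    ``spec`` is any object with ``fit(X_df, y) -> model`` where the model has
    ``predict(X_df)``; scaling is the model's own responsibility and is refit
    per training fold.
    """
    if len(features) < 1:
        raise MetricError("feature mask selects no features")
    if plan.n != table.n:
        raise FoldError(f"plan covers {plan.n} samples, table has {table.n}")
    Xdf = table.X[list(features)]
    y = table.target()
    oof = np.empty(table.n)
    fold_scores = []
    for f, (tr, te) in enumerate(plan.folds()):
        try:
            model = spec.fit(Xdf.iloc[tr], y[tr])
            pred = np.asarray(model.predict(Xdf.iloc[te]), dtype=float)
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {f}: {exc}") from exc
        oof[te] = pred
        fold_scores.append(rmse(pred, y[te]))
    pooled = rmse(oof, y)
    return CvResult(
        fold_rmse=fold_scores,
        pooled_rmse=pooled,
        mean_fold_rmse=float(np.mean(fold_scores)),
        predictions=oof,
    )


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

DEFAULT_C_GRID = (0.1, 0.5, 1.0, 1.5, 2.0, 2.3, 3.0, 5.0, 10.0)
DEFAULT_EPS_GRID = tuple(round(0.01 + 0.02 * i, 2) for i in range(13))  # 0.01..0.25


@dataclass
class GridSearchResult:
    """Exhaustive (C, epsilon) evaluation under k-fold CV."""

    curve: pd.DataFrame = field(repr=False)  # columns C, epsilon, mean_cv_rmse
    best_C: float
    best_epsilon: float
    best_rmse: float

    def to_csv(self, path_or_buf) -> None:
        self.curve.to_csv(path_or_buf, index=False)


def grid_search(
    table: DescriptorTable,
    features: list[str],
    kernel,
    plan: CvPlan,
    C_grid=DEFAULT_C_GRID,
    eps_grid=DEFAULT_EPS_GRID,
    spec_factory=None,
    tol: float = 1e-3,
) -> GridSearchResult:
    """Exhaustive grid search minimizing pooled CV RMSE.

    Ties are broken toward the smallest C then the smallest epsilon (the
    flatter, simpler model).  ``spec_factory(C, epsilon)`` may override the
    default SVR spec construction.
    """
    from .svr import SvrSpec  # local import to avoid cycle

    C_grid = list(C_grid)
    eps_grid = list(eps_grid)
    if not C_grid or not eps_grid:
        raise MetricError("empty hyperparameter grid")
    if any(c <= 0 for c in C_grid) or any(e < 0 for e in eps_grid):
        raise MetricError("C must be positive and epsilon non-negative")

    rows = []
    best = None
    for C in sorted(C_grid):
        for eps in sorted(eps_grid):
            spec = (
                spec_factory(C, eps)
                if spec_factory is not None
                else SvrSpec(kernel=kernel, C=C, epsilon=eps, tol=tol)
            )
            res = cross_validate(table, features, spec, plan)
            rows.append({"C": C, "epsilon": eps, "mean_cv_rmse": res.pooled_rmse})
            if best is None or res.pooled_rmse < best[2]:
                best = (C, eps, res.pooled_rmse)
    return GridSearchResult(
        curve=pd.DataFrame(rows),
        best_C=best[0],
        best_epsilon=best[1],
        best_rmse=best[2],
    )


@dataclass
class EvalReport:
    """Training/test error summary for one fitted model."""

    partition: str
    n: int
    rmse: float
    r2: float

    def as_dict(self) -> dict:
        return {
            "partition": self.partition,
            "n": self.n,
            "rmse": self.rmse,
            "r2": self.r2,
        }


def evaluate(pred, obs, partition: str = "train") -> EvalReport:
    """Bundle RMSE and R^2/Q^2 for one partition."""
    return EvalReport(
        partition=partition,
        n=len(np.asarray(obs)),
        rmse=rmse(pred, obs),
        r2=r_squared(pred, obs),
    )
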