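"""Partial least squares regression (NIPALS, single response).

The benchmark comparator for the SVR model.  Components are extracted by
the NIPALS iteration: each weight vector maximizes covariance between the
deflated predictor block and the response, scores are mutually orthogonal,
and the final model collapses to a linear coefficient vector on the original
descriptor scale, so prediction is a single dot product.

Inputs are z-scored (predictors) and centred (response) internally, mirroring
the SVR engine's scaling policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import CvPlan, cross_validate
from .svr import ScalingModel, _align_features
from .table import DescriptorTable


class PlsParameterError(ValueError):
    """Invalid component count or degenerate inputs."""


@dataclass
class PlsModel:
    """Fitted PLS model with per-component structures.

    ``coef``/``intercept`` are on the original descriptor scale, so
    ``predict`` does not need the score decomposition; the W/P/Q/T matrices
    are kept for diagnostics (orthogonality, explained variance).
    """

    n_components: int
    feature_names: list[str]
    scaling: ScalingModel
    y_mean: float
    weights: np.ndarray  # W (p, A)
    loadings: np.ndarray  # P (p, A)
    y_loadings: np.ndarray  # q (A,)
    scores: np.ndarray | None  # T (n, A), training scores
    coef: np.ndarray  # (p,), original scale
    intercept: float
    fitted_values: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X, feature_names: list[str] | None = None) -> np.ndarray:
        X = _align_features(X, self.feature_names, feature_names)
        return X @ self.coef + self.intercept


def train_pls(X, y, n_components: int, feature_names: list[str] | None = None) -> PlsModel:
    """Fit NIPALS PLS1 with ``n_components`` latent components.

    Raises :class:`PlsParameterError` if the requested number of components
    exceeds what the predictor block can support (its rank).
    """
    if hasattr(X, "columns"):
        feature_names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    A = int(n_components)
    if A < 1:
        raise PlsParameterError("need at least one component")
    if n <= A:
        raise PlsParameterError(f"n={n} must exceed n_components={A}")

    scaling = ScalingModel.fit(Xa, on_constant="unit")
    E = scaling.transform(Xa)
    y_mean = float(np.mean(y))
    f = y - y_mean

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    for a in range(A):
        wa = E.T @ f
        nw = np.linalg.norm(wa)
        if nw < 1e-12:
            raise PlsParameterError(
                f"component {a + 1} exceeds the rank of the predictor block"
            )
        wa /= nw
        t = E @ wa
        tt = float(t @ t)
        if tt < 1e-12:
            raise PlsParameterError(
                f"component {a + 1} exceeds the rank of the predictor block"
            )
        pa = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pa)
        f = f - qa * t
        W[:, a] = wa
        P[:, a] = pa
        q[a] = qa
        T[:, a] = t

    # collapse to direct-prediction coefficients: B_z = W (P'W)^-1 q
    coef_z = W @ np.linalg.solve(P.T @ W, q)
    coef = coef_z / scaling.sd
    intercept = y_mean - float(scaling.mean @ coef)

    model = PlsModel(
        n_components=A,
        feature_names=list(feature_names),
        scaling=scaling,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        intercept=intercept,
    )
    model.fitted_values = Xa @ coef + intercept
    return model


def predict_pls(model: PlsModel, X, feature_names: list[str] | None = None):
    """Functional alias for :meth:`PlsModel.predict`."""
    return model.predict(X, feature_names=feature_names)


@dataclass(frozen=True)
class PlsSpec:
    """Trainable PLS specification (fit/predict protocol for CV loops)."""

    n_components: int = 2

    def fit(self, X, y) -> PlsModel:
        return train_pls(X, y, self.n_components)


def select_components(
    table: DescriptorTable,
    features: list[str],
    plan: CvPlan,
    max_components: int | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose the component count minimizing pooled CV RMSE.

    Candidates run over 1..min(p, n-1) (or ``max_components``); ties break
    toward the smaller, simpler model.  Returns the winner and the full
    RMSE-per-candidate map.
    """
    p = len(features)
    hi = min(p, table.n - 1)
    if max_components is not None:
        hi = min(hi, max_components)
    if hi < 1:
        raise PlsParameterError("no feasible component count")
    scores: dict[int, float] = {}
    for A in range(1, hi + 1):
        try:
            res = cross_validate(table, features, PlsSpec(n_components=A), plan)
        except RuntimeError:
            break  # rank exhausted inside a fold; stop growing A
        scores[A] = res.pooled_rmse
    best = min(scores, key=lambda a: (scores[a], a))
    return best, scores
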