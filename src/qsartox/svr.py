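"""Epsilon-insensitive support vector regression.

The regression model is the kernel expansion

    f(x) = sum_i beta_i * k(x_i, x) + b,      beta_i = alpha_i - alpha_i*,

obtained by solving the epsilon-SVR dual

    min_{alpha, alpha*}  1/2 (a-a*)' K (a-a*) + eps * sum(a+a*) - y'(a-a*)
    s.t.  sum(a-a*) = 0,   0 <= a_i, a_i* <= C,

with a sequential-minimal-optimization (SMO) solver using maximal-violating-
pair working-set selection.  Residuals smaller than ``epsilon`` carry no loss,
so only points on or outside the epsilon-tube become support vectors.

Features are z-scored (mean 0, sd 1) on the training rows before entering the
kernel; mixing raw descriptor scales (molecular weight vs. orbital energies)
would otherwise let a single column dominate every kernel evaluation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

MODEL_FORMAT_VERSION = 1


class SvrParameterError(ValueError):
    """Invalid hyperparameter (C <= 0, epsilon < 0, bad kernel spec)."""


class SchemaError(ValueError):
    """Prediction-time feature columns do not match the trained model."""


class ModelLoadError(ValueError):
    """Serialized model is truncated, corrupted or of an unknown version."""


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    kind
        one of ``linear``, ``poly``, ``rbf``.
    degree
        polynomial degree d in (x.y + 1)^d; default 2.
    gamma
        RBF width in exp(-gamma * ||x-y||^2); ``None`` means 1/p at fit time.
    """

    kind: str = "poly"
    degree: int = 2
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "poly", "rbf"):
            raise SvrParameterError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "poly" and (int(self.degree) != self.degree or self.degree < 1):
            raise SvrParameterError("polynomial degree must be a positive integer")
        if self.gamma is not None and self.gamma <= 0:
            raise SvrParameterError("gamma must be positive")

    def resolve_gamma(self, p: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / p

    def matrix(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Kernel matrix K[i, j] = k(X[i], Y[j])."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[1] != Y.shape[1]:
            raise SchemaError(
                f"kernel dimension mismatch: {X.shape[1]} vs {Y.shape[1]}"
            )
        if self.kind == "linear":
            return X @ Y.T
        if self.kind == "poly":
            return (X @ Y.T + 1.0) ** self.degree
        g = self.resolve_gamma(X.shape[1])
        sq = (
            np.sum(X * X, axis=1)[:, None]
            - 2.0 * (X @ Y.T)
            + np.sum(Y * Y, axis=1)[None, :]
        )
        np.maximum(sq, 0.0, out=sq)
        return np.exp(-g * sq)


def kernel_eval(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    """Evaluate k(x, y) for two single vectors."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    return float(spec.matrix(x, y)[0, 0])


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalingModel:
    """Per-feature z-score parameters learned on training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, *, on_constant: str = "error") -> "ScalingModel":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            if on_constant == "error":
                bad = np.flatnonzero(sd == 0)
                raise SvrParameterError(
                    f"constant feature(s) at column index {bad.tolist()}; "
                    "drop them or pass on_constant='unit'"
                )
            # unit: leave constant columns centred but unscaled
            sd = np.where(sd == 0, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


# ---------------------------------------------------------------------------
# SMO solver
# ---------------------------------------------------------------------------


def _smo_loop(K, y, C, epsilon, tol, max_iter):  # pragma: no cover - jitted
    """SMO inner loop on the stacked (alpha, alpha*) vector.

    Index t < n is alpha_t (sign z=+1), t >= n is alpha*_{t-n} (z=-1).
    Written with explicit loops so numba can compile it; the pure-python
    fallback runs the same code object uncompiled.
    """
    n = len(y)
    theta = np.zeros(2 * n)
    grad = np.empty(2 * n)
    diag = np.empty(n)
    for t in range(n):
        grad[t] = epsilon - y[t]
        grad[n + t] = epsilon + y[t]
        diag[t] = K[t, t]
    snap = 1e-12 * max(1.0, C)

    it = 0
    while it < max_iter:
        it += 1
        # select i maximizing the violation score s_t = -z_t * grad_t over
        # the up-set, and track M = min score over the low-set for stopping
        m = -np.inf
        i = -1
        M = np.inf
        for t in range(2 * n):
            if t < n:
                s_t = -grad[t]
                if theta[t] < C and s_t > m:
                    m = s_t
                    i = t
                if theta[t] > 0.0 and s_t < M:
                    M = s_t
            else:
                s_t = grad[t]
                if theta[t] > 0.0 and s_t > m:
                    m = s_t
                    i = t
                if theta[t] < C and s_t < M:
                    M = s_t
        if i < 0 or m - M <= tol:
            it -= 1
            break

        i0 = i if i < n else i - n
        kii = K[i0, i0]
        # K is symmetric; K[i0, t] row reads are contiguous
        # second-order pair choice: among admissible j maximize b^2 / a where
        # b = s_i - s_j > 0 and a is the curvature along the update direction;
        # Q_ij = z_i z_j K[i0, j0] cancels the signs, so a is sign-free
        best_gain = -np.inf
        j = -1
        b_j = 0.0
        a_j = 1.0
        for t in range(2 * n):
            t0 = t if t < n else t - n
            if t < n:
                if theta[t] <= 0.0:
                    continue
                s_t = -grad[t]
            else:
                if theta[t] >= C:
                    continue
                s_t = grad[t]
            b_t = m - s_t
            if b_t <= 0.0:
                continue
            a_t = kii + diag[t0] - 2.0 * K[i0, t0]  # symmetric row read
            if a_t < 1e-12:
                a_t = 1e-12
            gain = b_t * b_t / a_t
            if gain > best_gain:
                best_gain = gain
                j = t
                b_j = b_t
                a_j = a_t
        if j < 0:
            it -= 1
            break

        j0 = j if j < n else j - n
        # step along (+z_i e_i, -z_j e_j); unconstrained optimum b/a, clipped
        step = b_j / a_j
        t_max_i = (C - theta[i]) if i < n else theta[i]
        t_max_j = theta[j] if j < n else (C - theta[j])
        if t_max_i < step:
            step = t_max_i
        if t_max_j < step:
            step = t_max_j
        theta[i] += step if i < n else -step
        theta[j] -= step if j < n else -step
        # snap exactly onto the box: a clipped update must not leave the
        # variable a rounding error inside the bound, or it stays selectable
        for idx in (i, j):
            if theta[idx] < snap:
                theta[idx] = 0.0
            elif theta[idx] > C - snap:
                theta[idx] = C
        # gradient update: grad_t += step * z_t * (K[t0,i0] - K[t0,j0]);
        # K rows i0 and j0 are read contiguously via symmetry
        for t in range(n):
            d = step * (K[i0, t] - K[j0, t])
            grad[t] += d
            grad[n + t] -= d

    return theta, grad, it


try:  # numba gives the inner loop C-like speed; plain python works without it
    from numba import njit as _njit

    _smo_loop_fast = _njit(cache=True, fastmath=False)(_smo_loop)
except ImportError:  # pragma: no cover
    _smo_loop_fast = None


def solve_svr_dual(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    epsilon: float,
    tol: float = 1e-6,
    max_iter: int | None = None,
) -> tuple[np.ndarray, float, int]:
    """Solve the epsilon-SVR dual by SMO with second-order pair selection.

    Returns ``(beta, b, n_iter)`` with ``beta = alpha - alpha*``.  The solver
    is deterministic: working pairs are chosen with first-index tie-breaking,
    so identical inputs give bit-identical output.
    """
    n = len(y)
    if C <= 0:
        raise SvrParameterError("C must be positive")
    if epsilon < 0:
        raise SvrParameterError("epsilon must be non-negative")
    if max_iter is None:
        max_iter = max(200_000, 4000 * n)
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)

    loop = _smo_loop_fast if _smo_loop_fast is not None else _smo_loop
    theta, grad, it = loop(K, y, float(C), float(epsilon), float(tol), max_iter)

    # bias from the midpoint of the KKT interval [M, m]
    z = np.concatenate([np.ones(n), -np.ones(n)])
    s = -z * grad
    up = np.where(z > 0, theta < C - 1e-12, theta > 1e-12)
    low = np.where(z > 0, theta > 1e-12, theta < C - 1e-12)
    m = np.max(np.where(up, s, -np.inf))
    M = np.min(np.where(low, s, np.inf))
    if not np.isfinite(m):
        m = M
    if not np.isfinite(M):
        M = m
    b = 0.5 * (m + M)

    beta = theta[:n] - theta[n:]
    return beta, float(b), it


def dual_objective(
    K: np.ndarray, y: np.ndarray, beta: np.ndarray, epsilon: float
) -> float:
    """Dual objective at the complementary point (alpha = beta+, alpha* = beta-)."""
    return float(
        0.5 * beta @ K @ beta + epsilon * np.sum(np.abs(beta)) - y @ beta
    )


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class SvrModel:
    """Trained epsilon-SVR model (support expansion plus scaling)."""

    kernel: KernelSpec
    C: float
    epsilon: float
    feature_names: list[str]
    scaling: ScalingModel
    support_vectors: np.ndarray  # (m, p), standardized coordinates
    beta: np.ndarray  # (m,), all non-zero
    bias: float
    fitted_values: np.ndarray | None = field(default=None, repr=False)
    dual_objective_: float | None = None

    @property
    def n_support(self) -> int:
        return len(self.beta)

    def decision_function(self, Xs: np.ndarray) -> np.ndarray:
        """Predict from already-standardized coordinates."""
        if self.n_support == 0:
            return np.full(len(Xs), self.bias)
        Kx = self.kernel.matrix(Xs, self.support_vectors)
        return Kx @ self.beta + self.bias

    def predict(self, X, feature_names: list[str] | None = None) -> np.ndarray:
        """Predict the target for raw (unscaled) descriptor rows.

        Accepts a pandas DataFrame (columns checked and reordered against the
        model schema) or a plain array whose columns are assumed to already
        follow ``feature_names``.
        """
        X = _align_features(X, self.feature_names, feature_names)
        return self.decision_function(self.scaling.transform(X))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "method": "svr",
            "kernel": {
                "kind": self.kernel.kind,
                "degree": self.kernel.degree,
                "gamma": self.kernel.gamma,
            },
            "C": self.C,
            "epsilon": self.epsilon,
            "feature_names": self.feature_names,
            "scaling": {
                "mean": self.scaling.mean.tolist(),
                "sd": self.scaling.sd.tolist(),
            },
            "support_vectors": self.support_vectors.tolist(),
            "beta": self.beta.tolist(),
            "bias": self.bias,
        }
        body = json.dumps(payload, sort_keys=True)
        checksum = hashlib.sha256(body.encode()).hexdigest()
        return json.dumps({"checksum": checksum, "model": payload}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SvrModel":
        try:
            doc = json.loads(text)
            checksum = doc["checksum"]
            payload = doc["model"]
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ModelLoadError(f"cannot parse model file: {exc}") from exc
        body = json.dumps(payload, sort_keys=True)
        if hashlib.sha256(body.encode()).hexdigest() != checksum:
            raise ModelLoadError("model checksum mismatch (file corrupted?)")
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ModelLoadError(
                f"unsupported model format version {payload.get('format_version')}"
            )
        if payload.get("method") != "svr":
            raise ModelLoadError(f"not an SVR model: method={payload.get('method')}")
        return cls(
            kernel=KernelSpec(**payload["kernel"]),
            C=payload["C"],
            epsilon=payload["epsilon"],
            feature_names=list(payload["feature_names"]),
            scaling=ScalingModel(
                mean=np.asarray(payload["scaling"]["mean"], dtype=float),
                sd=np.asarray(payload["scaling"]["sd"], dtype=float),
            ),
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            beta=np.asarray(payload["beta"], dtype=float),
            bias=payload["bias"],
        )


def _align_features(X, model_names: list[str], given_names: list[str] | None):
    """Return an (n, p) array whose columns follow ``model_names``."""
    if hasattr(X, "columns"):  # DataFrame
        missing = [c for c in model_names if c not in X.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")
        return X[model_names].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if given_names is not None and list(given_names) != list(model_names):
        if sorted(given_names) == sorted(model_names):
            order = [list(given_names).index(c) for c in model_names]
            return X[:, order]
        raise SchemaError(
            f"feature names {given_names} do not match model schema {model_names}"
        )
    if X.shape[1] != len(model_names):
        raise SchemaError(
            f"expected {len(model_names)} feature columns, got {X.shape[1]}"
        )
    return X


# ---------------------------------------------------------------------------
# training front end
# ---------------------------------------------------------------------------


def train_svr(
    X,
    y,
    kernel: KernelSpec | None = None,
    C: float = 1.0,
    epsilon: float = 0.1,
    tol: float = 1e-6,
    feature_names: list[str] | None = None,
    max_iter: int | None = None,
) -> SvrModel:
    """Train an epsilon-SVR model on raw descriptor rows.

    X may be a DataFrame (column names become the model schema) or an array
    with ``feature_names``.  Features are z-scored internally; the stored
    support vectors live in standardized coordinates.
    """
    kernel = kernel or KernelSpec()
    if hasattr(X, "columns"):
        feature_names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    if Xa.shape[0] != len(y):
        raise SvrParameterError("X and y have different numbers of rows")
    if Xa.shape[0] < 2:
        raise SvrParameterError("need at least 2 training rows")
    if not np.all(np.isfinite(Xa)) or not np.all(np.isfinite(y)):
        raise SvrParameterError("non-finite values in training data")

    scaling = ScalingModel.fit(Xa, on_constant="unit")
    Xs = scaling.transform(Xa)
    K = kernel.matrix(Xs, Xs)
    beta, b, _ = solve_svr_dual(K, y, C, epsilon, tol=tol, max_iter=max_iter)
    obj = dual_objective(K, y, beta, epsilon)

    sv = np.abs(beta) > 1e-12
    model = SvrModel(
        kernel=kernel,
        C=C,
        epsilon=epsilon,
        feature_names=list(feature_names),
        scaling=scaling,
        support_vectors=Xs[sv],
        beta=beta[sv],
        bias=b,
        dual_objective_=obj,
    )
    model.fitted_values = model.decision_function(Xs)
    return model


@dataclass(frozen=True)
class SvrSpec:
    """Trainable SVR specification (fit/predict protocol for CV loops)."""

    kernel: KernelSpec = field(default_factory=KernelSpec)
    C: float = 1.0
    epsilon: float = 0.1
    tol: float = 1e-3

    def fit(self, X, y) -> SvrModel:
        return train_svr(
            X, y, kernel=self.kernel, C=self.C, epsilon=self.epsilon, tol=self.tol
        )


def predict_svr(model: SvrModel, X, feature_names: list[str] | None = None):
    """Functional alias for :meth:`SvrModel.predict`."""
    return model.predict(X, feature_names=feature_names)


def serialize_model(model: SvrModel) -> str:
    return model.to_json()


def load_model(text: str) -> SvrModel:
    return SvrModel.from_json(text)
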