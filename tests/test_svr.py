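"""Epsilon-SVR engine: kernels, SMO solver vs. QP oracle, model contract."""

import numpy as np
import pandas as pd
import pytest

from qsartox.svr import (
    KernelSpec,
    ModelLoadError,
    ScalingModel,
    SchemaError,
    SvrParameterError,
    dual_objective,
    kernel_eval,
    load_model,
    serialize_model,
    solve_svr_dual,
    train_svr,
)

from oracles import svr_qp_oracle


class TestKernels:
    def test_poly_orthogonal_vectors(self):
        spec = KernelSpec("poly", degree=2)
        assert kernel_eval(spec, [1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_poly_direct_value(self):
        spec = KernelSpec("poly", degree=2)
        assert kernel_eval(spec, [1.0, 0.0], [1.0, 1.0]) == pytest.approx(4.0)

    def test_rbf_identical_points(self):
        spec = KernelSpec("rbf", gamma=0.7)
        assert kernel_eval(spec, [1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=3), rng.normal(size=3)
        for spec in (KernelSpec("linear"), KernelSpec("poly"), KernelSpec("rbf", gamma=0.5)):
            assert kernel_eval(spec, x, y) == pytest.approx(kernel_eval(spec, y, x))

    def test_dimension_mismatch(self):
        with pytest.raises(SchemaError):
            kernel_eval(KernelSpec("linear"), [1.0], [1.0, 2.0])

    def test_invalid_parameters(self):
        with pytest.raises(SvrParameterError):
            KernelSpec("poly", degree=0)
        with pytest.raises(SvrParameterError):
            KernelSpec("rbf", gamma=-1.0)
        with pytest.raises(SvrParameterError):
            KernelSpec("sigmoid")


class TestScaling:
    def test_zscore_roundtrip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(loc=5, scale=3, size=(40, 3))
        s = ScalingModel.fit(X)
        Z = s.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-12)

    def test_constant_feature_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(SvrParameterError):
            ScalingModel.fit(X)
        s = ScalingModel.fit(X, on_constant="unit")
        assert s.sd[0] == 1.0


class TestSolverAgainstOracle:
    @pytest.mark.parametrize("kind", ["linear", "poly", "rbf"])
    def test_dual_objective_and_predictions(self, kind):
        rng = np.random.default_rng(hash(kind) % 2**31)
        for _ in range(4):
            n, p = int(rng.integers(4, 11)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            spec = KernelSpec(kind, gamma=0.5 if kind == "rbf" else None)
            K = spec.matrix(X, X)
            C, eps = 2.0, 0.1
            beta, b, _ = solve_svr_dual(K, y, C, eps, tol=1e-9)
            obj = dual_objective(K, y, beta, eps)
            beta_o, b_o, obj_o = svr_qp_oracle(K, y, C, eps)
            assert obj <= obj_o + 1e-6
            assert abs(obj - obj_o) < 1e-6
            np.testing.assert_allclose(K @ beta + b, K @ beta_o + b_o, atol=1e-4)

    def test_dual_feasibility_invariants(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        K = KernelSpec("rbf", gamma=0.3).matrix(X, X)
        C = 1.5
        beta, _, _ = solve_svr_dual(K, y, C, 0.05, tol=1e-8)
        assert np.all(np.abs(beta) <= C + 1e-10)
        assert abs(beta.sum()) < 1e-8


class TestTraining:
    def test_constant_target_all_in_tube(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 2))
        model = train_svr(X, np.full(15, 2.5), KernelSpec("linear"), C=1.0, epsilon=0.1)
        assert model.n_support == 0
        np.testing.assert_allclose(model.predict(X), 2.5, atol=1e-9)

    def test_noiseless_linear_recovery(self):
        """y = w.x exactly: training RMSE stays within the 0.01 tube."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        y = X @ np.array([2.0, -1.0, 0.5])
        model = train_svr(X, y, KernelSpec("linear"), C=100.0, epsilon=0.01, tol=1e-8)
        res = np.abs(model.predict(X) - y)
        assert np.sqrt(np.mean(res**2)) <= 0.01 + 1e-6

    def test_interior_points_have_zero_beta(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 2))
        y = X @ np.array([1.0, 1.0]) + 0.02 * rng.normal(size=30)
        model = train_svr(X, y, KernelSpec("linear"), C=10.0, epsilon=0.2, tol=1e-8)
        # reconstruct full beta over training rows
        preds = model.predict(X)
        inside = np.abs(preds - y) < 0.2 - 1e-6
        # support vectors must all sit on or outside the tube boundary
        sv_rows = {tuple(np.round(v, 9)) for v in model.support_vectors}
        Xs = model.scaling.transform(X)
        for i in np.flatnonzero(inside):
            assert tuple(np.round(Xs[i], 9)) not in sv_rows

    def test_fitted_values_match_repredicition(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        model = train_svr(X, y, KernelSpec("poly"), C=2.0, epsilon=0.1)
        np.testing.assert_allclose(model.predict(X), model.fitted_values, atol=1e-9)

    def test_support_count_nonincreasing_in_epsilon(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 2))
        y = X @ np.array([1.0, 0.5]) + 0.1 * rng.normal(size=40)
        counts = [
            train_svr(X, y, KernelSpec("linear"), C=5.0, epsilon=e, tol=1e-8).n_support
            for e in (0.01, 0.05, 0.1, 0.3, 0.6)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_row_duplication_leaves_predictions_unchanged(self):
        """Duplicating every row while halving C is the same optimization."""
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        base = train_svr(X, y, KernelSpec("linear"), C=2.0, epsilon=0.1, tol=1e-9)
        dup = train_svr(
            np.vstack([X, X]), np.concatenate([y, y]),
            KernelSpec("linear"), C=1.0, epsilon=0.1, tol=1e-9,
        )
        probe = rng.normal(size=(6, 2))
        np.testing.assert_allclose(base.predict(probe), dup.predict(probe), atol=1e-4)

    def test_agrees_with_libsvm(self):
        """Cross-check predictions against an independent implementation."""
        sklearn_svm = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, -0.7, 0.3]) + 0.05 * rng.normal(size=60)
        model = train_svr(X, y, KernelSpec("rbf", gamma=0.4), C=3.0, epsilon=0.05,
                          tol=1e-9)
        Xs = model.scaling.transform(X)
        ref = sklearn_svm.SVR(kernel="rbf", gamma=0.4, C=3.0, epsilon=0.05, tol=1e-9)
        ref.fit(Xs, y)
        probe = rng.normal(size=(10, 3))
        np.testing.assert_allclose(
            model.predict(probe),
            ref.predict(model.scaling.transform(probe)),
            atol=1e-3,
        )

    def test_parameter_validation(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.zeros(10)
        with pytest.raises(SvrParameterError):
            train_svr(X, y, C=0.0)
        with pytest.raises(SvrParameterError):
            train_svr(X, y, epsilon=-0.1)
        with pytest.raises(SvrParameterError):
            train_svr(X[:1], y[:1])


class TestPrediction:
    def test_dataframe_schema_enforced(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["MW", "logP"])
        model = train_svr(X, rng.normal(size=20))
        with pytest.raises(SchemaError):
            model.predict(X.rename(columns={"logP": "LUMO"}))
        # column order must not matter for DataFrames
        np.testing.assert_allclose(
            model.predict(X), model.predict(X[["logP", "MW"]]), atol=1e-12
        )


class TestSerialization:
    def _model(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        y = X["a"].to_numpy() + 0.1 * rng.normal(size=25)
        return train_svr(X, y, KernelSpec("poly"), C=2.3, epsilon=0.11), X

    def test_round_trip_predictions_bit_identical(self):
        model, X = self._model()
        clone = load_model(serialize_model(model))
        np.testing.assert_array_equal(model.predict(X), clone.predict(X))

    def test_serialization_is_deterministic(self):
        model, X = self._model()
        again, _ = self._model()
        assert serialize_model(model) == serialize_model(again)

    def test_truncated_file_rejected(self):
        model, _ = self._model()
        text = serialize_model(model)
        with pytest.raises(ModelLoadError):
            load_model(text[: len(text) // 2])

    def test_checksum_mismatch_rejected(self):
        model, _ = self._model()
        text = serialize_model(model).replace('"bias": ', '"bias": 1')
        with pytest.raises(ModelLoadError):
            load_model(text)
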