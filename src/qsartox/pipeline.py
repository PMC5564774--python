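"""End-to-end workflow orchestration.

Reproduces the full modelling workflow on one descriptor table: seeded
train/test split, mRMR pre-selection, GA refinement, (C, epsilon) grid
search, final SVR fit, external validation, PLS benchmark, leave-one-out
ablation and sensitivity curves.  Every artifact lands in a run directory
stamped with the config hash and seed, and re-running an identical config
reproduces all numeric outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ga import GaConfig, ga_select
from .interpret import ablate, sensitivity_sweep, trend_statistic
from .metrics import (
    DEFAULT_C_GRID,
    DEFAULT_EPS_GRID,
    grid_search,
    make_folds,
    q_squared,
    r_squared,
    rmse,
)
from .mrmr import MrmrConfig, mrmr_rank
from .pls import PlsSpec, select_components, train_pls
from .svr import KernelSpec, SvrSpec, train_svr
from .synthetic import generate_split
from .table import DescriptorTable, read_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure with stage-tagged diagnostics."""


@dataclass
class PipelineConfig:
    """Configuration for one reproducible pipeline run."""

    table_path: str | None = None
    out_dir: str = "qsartox_run"
    seed: int = 0
    train_fraction: float = 500 / 581
    kernel: KernelSpec = field(default_factory=lambda: KernelSpec("poly"))
    mrmr: MrmrConfig = field(default_factory=MrmrConfig)
    ga: GaConfig | None = None
    C_grid: tuple = DEFAULT_C_GRID
    eps_grid: tuple = DEFAULT_EPS_GRID
    cv_folds: int = 5
    run_pls: bool = True
    run_ablation: bool = True
    run_sa: bool = True
    sa_grid_size: int = 50
    svr_tol: float = 1e-3

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            return o

        body = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(body.encode()).hexdigest()[:12]


def run_pipeline(
    config: PipelineConfig,
    table: DescriptorTable | None = None,
) -> dict:
    """Execute all stages; returns a result dict and writes artifacts.

    A pre-loaded ``table`` overrides ``config.table_path``.  All referenced
    columns are validated before any compute starts.
    """
    t_start = time.perf_counter()
    if table is None:
        if config.table_path is None:
            raise PipelineError("config: neither table_path nor table given")
        try:
            table = read_table(config.table_path)
        except Exception as exc:
            raise PipelineError(f"stage=read: {exc}") from exc
    if table.y is None:
        raise PipelineError("stage=read: table has no target column")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    results: dict = {"stamp": stamp}

    def stage(name):
        logger.info("stage %s (elapsed %.1fs)", name, time.perf_counter() - t_start)

    # -- split -------------------------------------------------------------
    stage("split")
    try:
        train, test = generate_split(table, config.train_fraction, config.seed)
    except Exception as exc:
        raise PipelineError(f"stage=split: {exc}") from exc
    results["n_train"], results["n_test"] = train.n, test.n

    # -- mRMR --------------------------------------------------------------
    stage("mrmr")
    try:
        pre = mrmr_rank(train, config.mrmr)
    except Exception as exc:
        raise PipelineError(f"stage=mrmr: {exc}") from exc
    results["mrmr_features"] = pre.features
    (out / "mrmr_ranking.json").write_text(
        json.dumps({**stamp, "features": pre.features, "scores": pre.scores}, indent=2)
    )

    # -- GA ----------------------------------------------------------------
    stage("ga")
    ga_cfg = config.ga or GaConfig(kernel=config.kernel, seed=config.seed)
    try:
        sel = ga_select(train, pre.features, ga_cfg)
    except Exception as exc:
        raise PipelineError(f"stage=ga: {exc}") from exc
    features = sel.features
    results["selected_features"] = features
    results["ga_fitness"] = sel.final_fitness
    (out / "selection.json").write_text(
        json.dumps(
            {**stamp, "features": features, "final_fitness": sel.final_fitness,
             "config": sel.config},
            indent=2,
        )
    )
    np.savetxt(
        out / "ga_fitness_trace.csv",
        np.column_stack([np.arange(len(sel.fitness_trace)), sel.fitness_trace]),
        delimiter=",",
        header="generation,best_fitness",
        comments="",
    )

    # -- tune --------------------------------------------------------------
    stage("tune")
    plan = make_folds(train.n, config.cv_folds, config.seed)
    try:
        gs = grid_search(
            train, features, config.kernel, plan,
            C_grid=config.C_grid, eps_grid=config.eps_grid, tol=config.svr_tol,
        )
    except Exception as exc:
        raise PipelineError(f"stage=tune: {exc}") from exc
    results["C"], results["epsilon"] = gs.best_C, gs.best_epsilon
    results["cv_rmse"] = gs.best_rmse
    gs.to_csv(out / "grid_search.csv")

    # -- train + validate --------------------------------------------------
    stage("train")
    try:
        model = train_svr(
            train.X[features], train.target(),
            kernel=config.kernel, C=gs.best_C, epsilon=gs.best_epsilon,
            tol=config.svr_tol,
        )
    except Exception as exc:
        raise PipelineError(f"stage=train: {exc}") from exc
    (out / "model.json").write_text(model.to_json())

    p_tr = model.predict(train.X[features])
    p_te = model.predict(test.X[features])
    results["svr"] = {
        "train_rmse": rmse(p_tr, train.target()),
        "train_r2": r_squared(p_tr, train.target()),
        "test_rmse": rmse(p_te, test.target()),
        "test_q2": q_squared(p_te, test.target()),
    }

    # -- PLS benchmark -----------------------------------------------------
    if config.run_pls:
        stage("pls")
        try:
            A, _ = select_components(train, features, plan)
            pls = train_pls(train.X[features], train.target(), A)
        except Exception as exc:
            raise PipelineError(f"stage=pls: {exc}") from exc
        q_tr = pls.predict(train.X[features])
        q_te = pls.predict(test.X[features])
        results["pls"] = {
            "n_components": A,
            "train_rmse": rmse(q_tr, train.target()),
            "train_r2": r_squared(q_tr, train.target()),
            "test_rmse": rmse(q_te, test.target()),
            "test_q2": q_squared(q_te, test.target()),
        }

    # -- ablation ----------------------------------------------------------
    if config.run_ablation and len(features) >= 2:
        stage("ablate")
        spec = SvrSpec(kernel=config.kernel, C=gs.best_C,
                       epsilon=gs.best_epsilon, tol=config.svr_tol)
        try:
            rep = ablate(train, test, features, spec)
        except Exception as exc:
            raise PipelineError(f"stage=ablate: {exc}") from exc
        rep.to_csv(out / "ablation.csv")
        results["ablation_rows"] = len(rep.rows)

    # -- sensitivity -------------------------------------------------------
    if config.run_sa:
        stage("sa")
        trends = {}
        for name in features:
            try:
                curve = sensitivity_sweep(model, train, name, config.sa_grid_size)
            except Exception as exc:
                raise PipelineError(f"stage=sa: {exc}") from exc
            curve.to_frame().to_csv(out / f"sa_{name}.csv", index=False)
            trends[name] = trend_statistic(curve)
        results["sa_trends"] = trends

    results["elapsed_s"] = round(time.perf_counter() - t_start, 2)
    (out / "results.json").write_text(json.dumps(results, indent=2, default=str))
    return results
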