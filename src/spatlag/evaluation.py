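"""Error metrics with Theil decomposition and repeated random-split validation.

Seven metrics are computed per (observed, predicted) pair: MSE, MAE, MAPE
(kept as a proportion; multiply by 100 for percent), the Theil inequality
coefficient, and the bias / variance / covariance proportions of the MSE.
The proportions use population (divide-by-n) standard deviations so that
BP + VP + CP = 1 holds exactly; CP is computed as 1 - BP - VP and
cross-checked against the direct covariance form.

The validation protocol redraws a uniform random train/test row split each
loop, refits every model (deriving fresh combination weights from validation
folds inside the training set — no test leakage), and reports the mean and
standard deviation of each metric over loops.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import models as M
from .design import lag_columns

log = logging.getLogger(__name__)

METRIC_NAMES = ("mse", "mae", "mape", "theil_ic", "bp", "vp", "cp")
DEFAULT_SPLIT_FRACTIONS = (0.9, 0.85, 0.8, 0.75, 0.7)


@dataclass(frozen=True)
class ErrorMetrics:
    mse: float
    mae: float
    mape: float
    theil_ic: float
    bp: float
    vp: float
    cp: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def error_metrics(observed, predicted) -> ErrorMetrics:
    """All seven metrics for one prediction vector.

    Requires strictly positive observed values (MAPE and the Theil
    denominator need them); zero-outcome records must be filtered upstream.
    With a perfect prediction the MSE-share proportions are undefined and
    reported as NaN.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("observed/predicted must be equal-length vectors, n >= 2")
    if np.any(y <= 0):
        raise ValueError(
            "observed values must be > 0 (apply filter_zero_outcomes upstream)"
        )
    err = y - yhat
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    mape = float(np.mean(np.abs(err) / y))
    theil = float(
        np.sqrt(mse) / (np.sqrt(np.mean(y**2)) + np.sqrt(np.mean(yhat**2)))
    )
    if mse == 0:
        return ErrorMetrics(0.0, 0.0, 0.0, 0.0, np.nan, np.nan, np.nan)
    sy = float(y.std())        # population SDs keep the decomposition exact
    syh = float(yhat.std())
    bp = float((yhat.mean() - y.mean()) ** 2) / mse
    vp = float((syh - sy) ** 2) / mse
    cp = 1.0 - bp - vp
    well_conditioned = mse > 1e-12 * (sy * sy + syh * syh)
    if sy > 0 and syh > 0 and well_conditioned:
        # cross-check against the direct covariance form; skipped when the
        # MSE is negligible relative to the series variance (the subtraction
        # sigma_yhat - sigma_y then loses all significant digits)
        r = float(np.corrcoef(y, yhat)[0, 1])
        cp_direct = 2.0 * (1.0 - r) * sy * syh / mse
        assert abs(cp - cp_direct) < 1e-6 * max(1.0, abs(cp)), (
            f"Theil decomposition inconsistency: {cp} vs {cp_direct}"
        )
    return ErrorMetrics(mse, mae, mape, theil, bp, vp, cp)


# ---------------------------------------------------------------------------
# Model specs and validation protocol


@dataclass(frozen=True)
class ModelSpec:
    name: str
    kind: str
    params: dict = field(default_factory=dict)


def default_model_specs() -> list[ModelSpec]:
    """The four component families with CV-selected linear hyperparameters.

    The model tree gets a larger leaf floor than its fit-level default: with
    18 collinear lag predictors a 20-row leaf regression is barely
    determined and occasionally extrapolates wildly out of sample.
    """
    return [
        ModelSpec("ridge", "ridge", {"penalty": None}),
        ModelSpec("pls", "pls", {"n_components": None}),
        ModelSpec("regression_tree", "regression_tree", {}),
        ModelSpec("model_tree", "model_tree", {"min_samples_leaf": 60}),
    ]


_FITTERS = {
    "ridge": M.fit_ridge,
    "pls": M.fit_pls,
    "regression_tree": M.fit_regression_tree,
    "model_tree": M.fit_model_tree,
}


def fit_spec(spec: ModelSpec, X, y, seed: int = 0):
    params = dict(spec.params)
    if spec.kind in ("ridge", "pls"):
        params.setdefault("seed", seed)
    return _FITTERS[spec.kind](X, y, **params)


def resolve_spec(spec: ModelSpec, X, y, seed: int = 0) -> ModelSpec:
    """Pin CV-selected hyperparameters on (X, y) so repeated fits within one
    validation loop (weight folds + final fit) use one setting."""
    if spec.kind == "ridge" and spec.params.get("penalty", 1.0) is None:
        mdl = M.fit_ridge(X, y, penalty=None, seed=seed)
        return ModelSpec(spec.name, spec.kind,
                         {**spec.params, "penalty": mdl.penalty})
    if spec.kind == "pls" and spec.params.get("n_components", 1) is None:
        mdl = M.fit_pls(X, y, n_components=None, seed=seed)
        return ModelSpec(spec.name, spec.kind,
                         {**spec.params, "n_components": max(mdl.n_components, 1)})
    return spec


@dataclass
class EvalReport:
    """Mean and SD of every metric over validation loops, per model."""

    summary: pd.DataFrame           # index model, columns metric_mean / metric_sd
    per_loop: pd.DataFrame          # loop, model, metrics
    loops: int
    train_fraction: float
    seed: int
    response: str
    combination_weight_log: list[dict] = field(default_factory=list)

    def mean(self, model: str, metric: str) -> float:
        return float(self.summary.loc[model, f"{metric}_mean"])

    def sd(self, model: str, metric: str) -> float:
        return float(self.summary.loc[model, f"{metric}_sd"])

    @property
    def model_names(self) -> list[str]:
        return list(self.summary.index)

    def best_model(self, metric: str = "mse") -> str:
        """Lowest mean metric; ties break toward the simpler family."""
        order = {"ridge": 0, "pls": 1, "regression_tree": 2, "model_tree": 3,
                 "combination": 4}
        col = self.summary[f"{metric}_mean"]
        return min(col.index, key=lambda m: (col[m], order.get(m, 99)))

    def to_table(self) -> pd.DataFrame:
        """'mean (SD)' cells, metrics as rows and models as columns."""
        rows = {}
        for metric in METRIC_NAMES:
            rows[metric] = {
                m: f"{self.mean(m, metric):.4g} ({self.sd(m, metric):.4g})"
                for m in self.model_names
            }
        return pd.DataFrame(rows).T[self.model_names]

    def to_json_dict(self) -> dict:
        return {
            "loops": self.loops,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "response": self.response,
            "summary": {
                m: {c: float(self.summary.loc[m, c]) for c in self.summary.columns}
                for m in self.summary.index
            },
            "combination_weight_log": self.combination_weight_log,
        }

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_table().to_csv(csv_path, index_label="metric")
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)


def _loop_once(
    X: np.ndarray,
    y: np.ndarray,
    specs: Sequence[ModelSpec],
    train_fraction: float,
    weight_folds: int,
    include_combination: bool,
    rng: np.random.Generator,
    fit_seed: int,
) -> tuple[dict[str, ErrorMetrics], dict | None]:
    n = y.size
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 2), n - 2)
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]

    specs = [resolve_spec(s, Xtr, ytr, seed=fit_seed) for s in specs]
    weights_entry = None
    metrics: dict[str, ErrorMetrics] = {}
    fitted = {}
    for spec in specs:
        fitted[spec.name] = fit_spec(spec, Xtr, ytr, seed=fit_seed)
        metrics[spec.name] = error_metrics(yte, fitted[spec.name].predict(Xte))

    if include_combination:
        if len(specs) < 2:
            raise ValueError("combination needs >= 2 component models")
        k = weight_folds
        fperm = rng.permutation(n_train)
        folds = [fperm[f::k] for f in range(k)]
        fold_mae = np.zeros((len(specs), k))
        for f, fold in enumerate(folds):
            mask = np.ones(n_train, dtype=bool)
            mask[fold] = False
            for m_idx, spec in enumerate(specs):
                mdl = fit_spec(spec, Xtr[mask], ytr[mask], seed=fit_seed)
                fold_mae[m_idx, f] = float(
                    np.mean(np.abs(ytr[fold] - mdl.predict(Xtr[fold])))
                )
        cw = M.combination_weights(fold_mae, [s.name for s in specs])
        comb_pred = np.column_stack(
            [fitted[s.name].predict(Xte) for s in specs]
        ) @ cw.weights
        metrics["combination"] = error_metrics(yte, comb_pred)
        weights_entry = cw.to_dict()
    return metrics, weights_entry


def run_validation(
    design: pd.DataFrame,
    model_specs: Sequence[ModelSpec] | None = None,
    response: str = "mortality_rate",
    train_fraction: float = 0.9,
    loops: int = 1000,
    seed: int = 0,
    weight_folds: int = 5,
    include_combination: bool = True,
    max_lag: int = 8,
) -> EvalReport:
    """Repeated random-split validation over design rows.

    Each loop draws a fresh uniform row split, fits every model on the
    training part (combination weights from ``weight_folds``-fold validation
    inside the training set), and scores all models on the test part.
    Fully reproducible given ``seed``; with a single loop SDs are reported
    as 0 by convention.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    specs = list(model_specs) if model_specs is not None else default_model_specs()
    X = design[lag_columns(max_lag)].to_numpy(dtype=float)
    y = design[response].to_numpy(dtype=float)
    n = y.size
    if n - int(round(train_fraction * n)) < 2:
        raise ValueError("test split would have fewer than 2 rows")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
    records = []
    weight_log = []
    for loop in range(loops):
        metrics, weights_entry = _loop_once(
            X, y, specs, train_fraction, weight_folds, include_combination,
            rng, fit_seed=seed,
        )
        for name, em in metrics.items():
            records.append({"loop": loop, "model": name, **em.as_dict()})
        if weights_entry is not None:
            weight_log.append({"loop": loop, **weights_entry})

    per_loop = pd.DataFrame(records)
    agg_mean = per_loop.groupby("model", sort=False)[list(METRIC_NAMES)].mean()
    if loops > 1:
        agg_sd = per_loop.groupby("model", sort=False)[list(METRIC_NAMES)].std(ddof=1)
    else:
        agg_sd = agg_mean * 0.0
    summary = pd.concat(
        {"mean": agg_mean, "sd": agg_sd}, axis=1
    )
    summary.columns = [f"{metric}_{stat}" for stat, metric in summary.columns]
    return EvalReport(
        summary=summary,
        per_loop=per_loop,
        loops=loops,
        train_fraction=train_fraction,
        seed=seed,
        response=response,
        combination_weight_log=weight_log,
    )


def split_sensitivity(
    design: pd.DataFrame,
    model_specs: Sequence[ModelSpec] | None = None,
    fractions: Sequence[float] = DEFAULT_SPLIT_FRACTIONS,
    response: str = "mortality_rate",
    loops: int = 1000,
    seed: int = 0,
    **kwargs,
) -> list[EvalReport]:
    """One full validation run per training fraction, identical seed each."""
    reports = []
    for frac in fractions:
        rep = run_validation(
            design,
            model_specs=model_specs,
            response=response,
            train_fraction=frac,
            loops=loops,
            seed=seed,
            **kwargs,
        )
        log.info(
            "split_sensitivity: fraction %.2f best model by MSE: %s",
            frac,
            rep.best_model("mse"),
        )
        reports.append(rep)
    return reports
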