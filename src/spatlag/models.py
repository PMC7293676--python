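"""The five forecasting models, implemented from scratch.

* ridge regression (closed-form penalized normal equations),
* partial least squares (NIPALS, PLS1),
* CART-style regression tree,
* model tree (CART splits with ridge-stabilized linear leaves),
* convex combination weighted by inverse coefficient of variation of
  validation-fold errors.

All fits are deterministic; hyperparameter selection, where enabled, uses an
internal seeded K-fold cross-validation.  ``lambda_reg`` elsewhere in this
package names a *regional lag coefficient*; the ridge penalty is always
called ``penalty`` / ``ridge_penalty`` to avoid the collision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RIDGE_PENALTY_GRID = tuple(10.0**k for k in range(-3, 4))
MODEL_KINDS = ("ridge", "pls", "regression_tree", "model_tree", "combination")


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, None


def _check_features(model, X) -> np.ndarray:
    M, names = _as_matrix(X)
    if names is not None and model.feature_names is not None:
        if names != list(model.feature_names):
            raise ValueError(
                f"feature names at predict time {names} do not match "
                f"training features {list(model.feature_names)}"
            )
    if M.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {M.shape[1]}"
        )
    return M


def _kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[f::k] for f in range(k)]


# ---------------------------------------------------------------------------
# Ridge


@dataclass
class RidgeModel:
    kind = "ridge"
    coef: np.ndarray          # original-scale slopes, zeros for dropped columns
    intercept: float
    penalty: float
    feature_names: tuple[str, ...] | None
    training_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.coef.size

    def predict(self, X) -> np.ndarray:
        M = _check_features(self, X)
        return M @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "penalty": self.penalty,
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "training_meta": self.training_meta,
        }


def _solve_ridge_standardized(
    Z: np.ndarray, yc: np.ndarray, penalty: float
) -> np.ndarray:
    p = Z.shape[1]
    A = Z.T @ Z + penalty * np.eye(p)
    return np.linalg.solve(A, Z.T @ yc)


def fit_ridge(
    X,
    y,
    penalty: float | None = 1.0,
    fit_intercept: bool = True,
    standardize: bool = True,
    cv_folds: int = 5,
    cv_grid: Sequence[float] = RIDGE_PENALTY_GRID,
    seed: int = 0,
) -> RidgeModel:
    """Closed-form ridge with internally standardized predictors.

    The intercept is never penalized.  ``penalty=None`` selects the penalty
    from ``cv_grid`` by seeded K-fold cross-validation (lowest mean squared
    error; ties go to the smaller penalty).
    """
    M, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = M.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    if penalty is not None and penalty < 0:
        raise ValueError("ridge penalty must be >= 0")

    if penalty is None:
        folds = _kfold_indices(n, min(cv_folds, n), seed)
        best = (np.inf, None)
        for lam in cv_grid:
            errs = []
            for f in folds:
                mask = np.ones(n, dtype=bool)
                mask[f] = False
                if mask.sum() < 2 or len(f) == 0:
                    continue
                m = fit_ridge(
                    M[mask], y[mask], penalty=lam,
                    fit_intercept=fit_intercept, standardize=standardize,
                )
                errs.append(float(np.mean((y[f] - m.predict(M[f])) ** 2)))
            score = float(np.mean(errs))
            if score < best[0]:
                best = (score, lam)
        penalty = best[1]

    meta = {"n": n, "penalty": penalty, "standardize": standardize,
            "fit_intercept": fit_intercept}
    if not fit_intercept and not standardize:
        coef = _solve_ridge_standardized(M, y, penalty)
        return RidgeModel(coef=coef, intercept=0.0, penalty=penalty,
                          feature_names=tuple(names) if names else None,
                          training_meta=meta)

    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant predictor column(s)",
            stacklevel=2,
        )
    if standardize:
        Z = (M[:, keep] - mu[keep]) / sd[keep]
    else:
        Z = M[:, keep] - mu[keep]
    ybar = y.mean()
    b = _solve_ridge_standardized(Z, y - ybar, penalty)
    coef = np.zeros(p)
    coef[keep] = b / sd[keep] if standardize else b
    intercept = ybar - float(mu @ coef)
    return RidgeModel(coef=coef, intercept=intercept, penalty=penalty,
                      feature_names=tuple(names) if names else None,
                      training_meta=meta)


# ---------------------------------------------------------------------------
# Partial least squares (NIPALS, single response)


@dataclass
class PLSModel:
    kind = "pls"
    coef: np.ndarray
    intercept: float
    n_components: int
    x_weights: np.ndarray     # standardized-scale weight vectors, p x A
    x_loadings: np.ndarray    # p x A
    y_loadings: np.ndarray    # A
    feature_names: tuple[str, ...] | None
    training_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.coef.size

    def predict(self, X) -> np.ndarray:
        M = _check_features(self, X)
        return M @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "n_components": self.n_components,
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "training_meta": self.training_meta,
        }


def fit_pls(
    X,
    y,
    n_components: int | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> PLSModel:
    """NIPALS PLS1 on standardized predictors and centered response.

    Components sequentially maximize covariance with the response, with
    deflation after each extraction.  ``n_components=None`` selects the
    count by seeded K-fold cross-validation over 1..min(10, p).
    Requesting more components than the data support truncates with a
    warning.
    """
    M, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = M.shape
    if n < 2:
        raise ValueError("need at least 2 rows")

    if n_components is None:
        grid = range(1, min(10, p) + 1)
        folds = _kfold_indices(n, min(cv_folds, n), seed)
        best = (np.inf, 1)
        for a in grid:
            errs = []
            for f in folds:
                mask = np.ones(n, dtype=bool)
                mask[f] = False
                if mask.sum() < 2 or len(f) == 0:
                    continue
                m = fit_pls(M[mask], y[mask], n_components=a)
                errs.append(float(np.mean((y[f] - m.predict(M[f])) ** 2)))
            score = float(np.mean(errs))
            if score < best[0]:
                best = (score, a)
        n_components = best[1]
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (M - mu) / sd_safe
    ybar = y.mean()
    yr = y - ybar

    Ws, Ps, Qs = [], [], []
    Zd = Z.copy()
    yd = yr.copy()
    tol = 1e-12 * max(1.0, float(np.abs(Z).max()) ** 2)
    extracted = 0
    for _ in range(n_components):
        w = Zd.T @ yd
        wnorm = np.linalg.norm(w)
        if wnorm <= 1e-12 * max(1.0, np.linalg.norm(yd)) or wnorm == 0:
            break
        w = w / wnorm
        t = Zd @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        pvec = Zd.T @ t / tt
        q = float(yd @ t) / tt
        Zd = Zd - np.outer(t, pvec)
        yd = yd - q * t
        Ws.append(w)
        Ps.append(pvec)
        Qs.append(q)
        extracted += 1
    if extracted < n_components:
        warnings.warn(
            f"PLS truncated at {extracted} component(s) "
            f"(requested {n_components}: remaining covariance exhausted)",
            stacklevel=2,
        )
    if extracted == 0:
        # no exploitable covariance: predict the training mean
        coef = np.zeros(p)
        return PLSModel(coef=coef, intercept=ybar, n_components=0,
                        x_weights=np.zeros((p, 0)), x_loadings=np.zeros((p, 0)),
                        y_loadings=np.zeros(0),
                        feature_names=tuple(names) if names else None,
                        training_meta={"n": n})
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.asarray(Qs)
    B_std = W @ np.linalg.solve(P.T @ W, q)
    coef = B_std / sd_safe
    coef[sd == 0] = 0.0
    intercept = ybar - float(mu @ coef)
    return PLSModel(coef=coef, intercept=intercept, n_components=extracted,
                    x_weights=W, x_loadings=P, y_loadings=q,
                    feature_names=tuple(names) if names else None,
                    training_meta={"n": n, "requested_components": n_components})


# ---------------------------------------------------------------------------
# Trees


def _best_sse_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[float, int, float] | None:
    """Exhaustive best binary split by total within-child SSE.

    Candidates are midpoints between consecutive distinct sorted values.
    Ties in SSE reduction break to the lowest feature index, then the lowest
    threshold (argmax returns the first, i.e. smallest, threshold within a
    feature; strictly-greater comparison keeps the earliest feature).
    Returns (sse_reduction, feature, threshold) or None.
    """
    n, p = X.shape
    base = float(((y - y.mean()) ** 2).sum())
    order = np.argsort(X, axis=0, kind="mergesort")
    xv = np.take_along_axis(X, order, axis=0)      # n x p, each column sorted
    yv = y[order]
    c1 = np.cumsum(yv, axis=0)
    c2 = np.cumsum(yv * yv, axis=0)
    nl = np.arange(1, n, dtype=float)[:, None]
    nr = n - nl
    valid = (xv[1:] > xv[:-1]) & (nl >= min_leaf) & (nr >= min_leaf)
    sse_l = c2[:-1] - c1[:-1] ** 2 / nl
    sse_r = (c2[-1] - c2[:-1]) - (c1[-1] - c1[:-1]) ** 2 / nr
    red = np.where(valid, base - (sse_l + sse_r), -np.inf)
    return _argmax_split(red, xv, base)


def _argmax_split(red: np.ndarray, xv: np.ndarray, scale: float):
    """Deterministic winner of a (candidates x features) reduction matrix.

    Reductions within a relative 1e-9 band of the maximum count as tied
    (identical partitions reached through different features differ only by
    float noise); ties break to the lowest feature index, then the lowest
    threshold, via the first flat hit in feature-major order.
    """
    n = xv.shape[0]
    top = float(red.max())
    if not np.isfinite(top) or top <= 1e-12 * max(scale, 1.0):
        return None
    tol = 1e-9 * max(top, 1e-300)
    flat = int(np.argmax(red.T >= top - tol))
    j, i = divmod(flat, n - 1)
    return float(red[i, j]), int(j), float(0.5 * (xv[i, j] + xv[i + 1, j]))


def _prefix_sse_simple(xv: np.ndarray, yv: np.ndarray) -> np.ndarray:
    """SSE of a simple linear regression of y on x over every prefix of each
    sorted column; prefix k uses the first k points (k = 1..n).

    ``xv``/``yv`` are (n, p); returns (n, p).
    """
    n = yv.shape[0]
    k = np.arange(1, n + 1, dtype=float)[:, None]
    sx = np.cumsum(xv, axis=0)
    sxx = np.cumsum(xv * xv, axis=0)
    sy = np.cumsum(yv, axis=0)
    syy = np.cumsum(yv * yv, axis=0)
    sxy = np.cumsum(xv * yv, axis=0)
    syy_c = syy - sy * sy / k
    sxx_c = sxx - sx * sx / k
    sxy_c = sxy - sx * sy / k
    sse = syy_c - np.where(sxx_c > 0, sxy_c * sxy_c / np.maximum(sxx_c, 1e-300), 0.0)
    return np.maximum(sse, 0.0)


def _best_linear_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[float, int, float] | None:
    """Best split by total within-child SSE of *simple* regressions on the
    split feature (closed form, so every candidate threshold is scanned).

    Used by the model tree, where constant-mean SSE would keep splitting
    noiseless piecewise-linear data long past the breakpoints.  Reduction is
    measured against the same simple regression fitted to the whole node;
    ties break to the lowest feature index, then the lowest threshold.
    """
    n, p = X.shape
    order = np.argsort(X, axis=0, kind="mergesort")
    xv = np.take_along_axis(X, order, axis=0)
    yv = y[order]
    sse_l = _prefix_sse_simple(xv, yv)
    sse_r = _prefix_sse_simple(xv[::-1], yv[::-1])[::-1]
    base = sse_l[-1]                               # per-feature node baseline
    nl = np.arange(1, n, dtype=float)[:, None]
    valid = (xv[1:] > xv[:-1]) & (nl >= min_leaf) & (n - nl >= min_leaf)
    red = np.where(valid, base - (sse_l[:-1] + sse_r[1:]), -np.inf)
    return _argmax_split(red, xv, float(base.max()))


def _fit_leaf_mean(X: np.ndarray, y: np.ndarray) -> dict:
    return {"leaf": True, "value": float(y.mean()), "n": int(y.size)}


def _fit_leaf_linear(X: np.ndarray, y: np.ndarray, penalty: float) -> dict:
    if np.ptp(y) == 0:
        return {"leaf": True, "coef": [0.0] * X.shape[1],
                "intercept": float(y[0]), "n": int(y.size)}
    mu = X.mean(axis=0)
    Xc = X - mu
    b = np.linalg.solve(Xc.T @ Xc + penalty * np.eye(X.shape[1]), Xc.T @ (y - y.mean()))
    intercept = float(y.mean() - mu @ b)
    return {
        "leaf": True,
        "coef": b.tolist(),
        "intercept": intercept,
        "n": int(y.size),
    }


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    depth: int,
    max_depth: int,
    min_leaf: int,
    leaf_fitter: Callable[[np.ndarray, np.ndarray], dict],
    split_on_leaf_residuals: bool = False,
) -> dict:
    if depth >= max_depth or y.size < 2 * min_leaf or np.ptp(y) == 0:
        return leaf_fitter(X, y)
    if split_on_leaf_residuals:
        # model tree: stop when the node's full linear model is already an
        # (essentially) exact fit; otherwise split where children's linear
        # fits improve most
        leaf = leaf_fitter(X, y)
        resid = y - (leaf["intercept"] + X @ np.asarray(leaf["coef"]))
        if float(resid @ resid) <= 1e-10 * max(float(y @ y), 1.0):
            return leaf
        split = _best_linear_split(X, y, min_leaf)
    else:
        split = _best_sse_split(X, y, min_leaf)
    if split is None:
        return leaf_fitter(X, y)
    _, j, thr = split
    left = X[:, j] <= thr
    kids = [
        _grow_tree(X[m], y[m], depth + 1, max_depth, min_leaf, leaf_fitter,
                   split_on_leaf_residuals)
        for m in (left, ~left)
    ]
    return {
        "leaf": False,
        "feature": int(j),
        "threshold": float(thr),
        "n": int(y.size),
        "left": kids[0],
        "right": kids[1],
    }


def _predict_node(node: dict, row: np.ndarray) -> float:
    while not node["leaf"]:
        node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
    if "coef" in node:
        return node["intercept"] + float(np.dot(node["coef"], row))
    return node["value"]


@dataclass
class TreeModel:
    kind: str                  # regression_tree | model_tree
    root: dict
    n_features: int
    feature_names: tuple[str, ...] | None
    training_meta: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        M = _check_features(self, X)
        return np.array([_predict_node(self.root, row) for row in M])

    def depth(self) -> int:
        def _d(node):
            if node["leaf"]:
                return 0
            return 1 + max(_d(node["left"]), _d(node["right"]))
        return _d(self.root)

    def n_leaves(self) -> int:
        def _c(node):
            if node["leaf"]:
                return 1
            return _c(node["left"]) + _c(node["right"])
        return _c(self.root)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "root": self.root,
            "n_features": self.n_features,
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "training_meta": self.training_meta,
        }


def fit_regression_tree(
    X, y, min_samples_leaf: int = 5, max_depth: int = 10
) -> TreeModel:
    """CART-style tree: recursive binary splits minimizing within-node SSE,
    constant (mean) leaves."""
    M, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if y.size < 2 * min_samples_leaf:
        raise ValueError("need n >= 2 * min_samples_leaf rows")
    root = _grow_tree(M, y, 0, max_depth, min_samples_leaf, _fit_leaf_mean)
    return TreeModel(kind="regression_tree", root=root, n_features=M.shape[1],
                     feature_names=tuple(names) if names else None,
                     training_meta={"n": y.size, "min_samples_leaf": min_samples_leaf,
                                    "max_depth": max_depth})


def fit_model_tree(
    X,
    y,
    min_samples_leaf: int = 20,
    max_depth: int = 5,
    leaf_penalty: float = 1e-6,
) -> TreeModel:
    """Tree with the same SSE split search but a ridge-stabilized linear
    model (penalty ``leaf_penalty``) on all features in each leaf."""
    M, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if min_samples_leaf <= M.shape[1]:
        raise ValueError(
            "min_samples_leaf must exceed the number of features "
            "(leaf regressions must be determined)"
        )
    if y.size < 2 * min_samples_leaf:
        raise ValueError("need n >= 2 * min_samples_leaf rows")
    fitter = lambda Xs, ys: _fit_leaf_linear(Xs, ys, leaf_penalty)
    root = _grow_tree(M, y, 0, max_depth, min_samples_leaf, fitter,
                      split_on_leaf_residuals=True)
    return TreeModel(kind="model_tree", root=root, n_features=M.shape[1],
                     feature_names=tuple(names) if names else None,
                     training_meta={"n": y.size, "min_samples_leaf": min_samples_leaf,
                                    "max_depth": max_depth,
                                    "leaf_penalty": leaf_penalty})


# ---------------------------------------------------------------------------
# Combination


@dataclass
class CombinationWeights:
    """Convex weights from inverse coefficients of variation of fold errors."""

    model_names: tuple[str, ...]
    weights: np.ndarray
    cv_values: np.ndarray

    def to_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "weights": self.weights.tolist(),
            "cv_values": self.cv_values.tolist(),
        }


def combination_weights(
    fold_abs_errors: np.ndarray, model_names: Sequence[str] | None = None
) -> CombinationWeights:
    """Weights from a (models x folds) matrix of fold mean absolute errors.

    CV_m = SD(fold errors of m) / mean(fold errors of m); weight_m
    proportional to 1/CV_m.  Models with CV_m = 0 (perfectly stable) share
    the whole weight equally; otherwise weights normalize to 1.
    """
    E = np.asarray(fold_abs_errors, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2:
        raise ValueError("need a (models x folds) matrix with >= 2 models")
    if E.shape[1] < 2:
        raise ValueError("need >= 2 folds")
    means = E.mean(axis=1)
    if np.all(E == 0):
        raise ValueError("all fold errors are zero")
    if np.any(means <= 0):
        raise ValueError("every model's mean fold error must be > 0")
    cv = E.std(axis=1, ddof=1) / means
    names = tuple(model_names) if model_names else tuple(
        f"model_{m}" for m in range(E.shape[0])
    )
    zero = cv == 0
    if zero.any():
        w = np.where(zero, 1.0 / zero.sum(), 0.0)
    else:
        inv = 1.0 / cv
        w = inv / inv.sum()
    return CombinationWeights(model_names=names, weights=w, cv_values=cv)


@dataclass
class CombinationModel:
    kind = "combination"
    components: tuple
    weights: CombinationWeights
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.components) != self.weights.weights.size:
            raise ValueError("weights do not align with components")

    @property
    def n_features(self) -> int:
        return self.components[0].n_features

    @property
    def feature_names(self):
        return self.components[0].feature_names

    def predict(self, X) -> np.ndarray:
        preds = np.column_stack([m.predict(X) for m in self.components])
        return preds @ self.weights.weights

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "weights": self.weights.to_dict(),
            "components": [m.to_dict() for m in self.components],
            "training_meta": self.training_meta,
        }


def predict_combination(components, weights: CombinationWeights, X) -> np.ndarray:
    """Convex combination of component predictions."""
    if len(components) != weights.weights.size:
        raise ValueError("weights do not align with components")
    return CombinationModel(tuple(components), weights).predict(X)
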