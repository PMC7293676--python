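"""Ordinary Kriging of area-level predictions to a gridded surface.

Variogram estimation uses the Matheron estimator over equal-width distance
bins; model fitting is weighted least squares (pair-count weights) over
spherical or exponential forms with a deterministic multi-start.  Prediction
solves the ordinary-Kriging system (semivariance matrix + unbiasedness
constraint) per target cell on the k nearest data points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass


import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree, distance_matrix

from .exposure import ExposureGrid, NODATA_DEFAULT

log = logging.getLogger(__name__)

VARIOGRAM_MODELS = ("spherical", "exponential")


@dataclass
class EmpiricalVariogram:
    lags: np.ndarray          # bin-center distances
    semivariance: np.ndarray
    pair_counts: np.ndarray


@dataclass
class VariogramModel:
    """Fitted variogram: ``sill`` is the total plateau (nugget included)."""

    model: str
    nugget: float
    sill: float
    range_: float
    empirical: EmpiricalVariogram | None = None

    def __post_init__(self) -> None:
        if self.model not in VARIOGRAM_MODELS:
            raise ValueError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0 or self.sill <= 0 or self.range_ <= 0:
            raise ValueError("need nugget >= 0, sill > 0, range > 0")
        if self.sill < self.nugget:
            raise ValueError("sill must be >= nugget")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        partial = self.sill - self.nugget
        if self.model == "spherical":
            u = np.clip(h / self.range_, 0.0, 1.0)
            gamma = self.nugget + partial * (1.5 * u - 0.5 * u**3)
        else:
            gamma = self.nugget + partial * (1.0 - np.exp(-h / self.range_))
        return np.where(h == 0, 0.0, gamma)


@dataclass
class KrigedSurface:
    grid: ExposureGrid        # predicted rate per 100,000
    variance: np.ndarray      # kriging variance, grid-shaped
    outcome: str
    year: int
    failed_cells: int = 0


def empirical_variogram(
    points: np.ndarray,
    values: np.ndarray,
    n_lags: int = 12,
    max_dist: float | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator gamma(h) = sum (z_i - z_j)^2 / (2 |N(h)|) over
    equal-width bins up to ``max_dist`` (default: half the bounding-box
    diagonal).  Empty bins are omitted."""
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if pts.shape[0] < 10:
        log.warning(
            "empirical_variogram: only %d points; estimates will be unstable",
            pts.shape[0],
        )
    span = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.hypot(*span))
    if diag == 0:
        raise ValueError("all points coincident")
    if max_dist is None:
        max_dist = diag / 2
    iu = np.triu_indices(pts.shape[0], k=1)
    d = distance_matrix(pts, pts)[iu]
    sq = (z[:, None] - z[None, :])[iu] ** 2
    keep = (d > 0) & (d <= max_dist)
    d, sq = d[keep], sq[keep]
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_lags - 1)
    lags, gammas, counts = [], [], []
    for b in range(n_lags):
        sel = which == b
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        lags.append(0.5 * (edges[b] + edges[b + 1]))
        gammas.append(float(sq[sel].sum()) / (2.0 * cnt))
        counts.append(cnt)
    return EmpiricalVariogram(
        lags=np.asarray(lags), semivariance=np.asarray(gammas),
        pair_counts=np.asarray(counts),
    )


def _model_curve(model: str, params: np.ndarray, h: np.ndarray) -> np.ndarray:
    nugget, psill, rng_ = params
    if model == "spherical":
        u = np.clip(h / rng_, 0.0, 1.0)
        return nugget + psill * (1.5 * u - 0.5 * u**3)
    return nugget + psill * (1.0 - np.exp(-h / rng_))


def fit_variogram(
    empirical: EmpiricalVariogram, model: str = "spherical"
) -> VariogramModel:
    """Pair-count-weighted least squares over (nugget, partial sill, range).

    Deterministic multi-start over a fixed grid of initial values; if the
    requested model cannot be fitted the exponential form is tried as a
    fallback (logged).
    """
    if empirical.lags.size < 3:
        raise ValueError("need at least 3 empirical variogram points")

    def _try(model_name: str) -> VariogramModel | None:
        h = empirical.lags
        g = empirical.semivariance
        w = np.sqrt(empirical.pair_counts.astype(float))
        gmax = max(float(g.max()), 1e-12)
        hmax = float(h.max())
        best = None
        for r0 in (0.25 * hmax, 0.5 * hmax, hmax):
            for n0 in (0.0, 0.5 * gmax):
                x0 = np.array([n0, max(gmax - n0, 1e-10), r0])
                try:
                    res = least_squares(
                        lambda p: w * (_model_curve(model_name, p, h) - g),
                        x0,
                        bounds=([0.0, 1e-12, 1e-12 * max(hmax, 1.0)],
                                [np.inf, np.inf, np.inf]),
                        method="trf",
                        max_nfev=2000,
                    )
                except Exception:
                    continue
                cost = float(res.cost)
                if best is None or cost < best[0] - 1e-15:
                    best = (cost, res.x)
        if best is None:
            return None
        nugget, psill, rng_ = best[1]
        return VariogramModel(
            model=model_name, nugget=float(nugget),
            sill=float(nugget + psill), range_=float(rng_),
            empirical=empirical,
        )

    fitted = _try(model)
    if fitted is None and model != "exponential":
        log.warning("fit_variogram: %s fit failed, falling back to exponential", model)
        fitted = _try("exponential")
    if fitted is None:
        raise RuntimeError("variogram fit failed for all models")
    return fitted


def kriging_weights(
    neighbors: np.ndarray,
    target: np.ndarray,
    variogram: VariogramModel,
    jitter: float = 1e-10,
) -> tuple[np.ndarray, float] | None:
    """Solve the ordinary-Kriging system for one target location.

    Returns (weights, lagrange multiplier) or None when the system stays
    singular after one jitter retry.
    """
    k = neighbors.shape[0]
    G = variogram(distance_matrix(neighbors, neighbors))
    g0 = variogram(np.linalg.norm(neighbors - target, axis=1))
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    b = np.append(g0, 1.0)
    for attempt in (0.0, jitter):
        try:
            sol = np.linalg.solve(A + attempt * np.eye(k + 1), b)
            return sol[:k], float(sol[k])
        except np.linalg.LinAlgError:
            continue
    return None


def ordinary_kriging(
    points: np.ndarray,
    values: np.ndarray,
    variogram: VariogramModel,
    target_grid: ExposureGrid,
    k_neighbors: int = 25,
    outcome: str = "mortality",
) -> KrigedSurface:
    """Krige point data onto the geometry of ``target_grid``.

    Per cell the system uses the ``k_neighbors`` nearest data points;
    singular cells become NODATA (counted and logged).
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 data points")
    spread = np.ptp(pts, axis=0)
    if np.count_nonzero(spread > 0) < 2:
        raise ValueError("data points are collinear; kriging system degenerate")
    tree = cKDTree(pts)
    lons, lats = target_grid.cell_centers()
    targets = np.column_stack([lons.ravel(), lats.ravel()])
    k = min(k_neighbors, pts.shape[0])
    _, idx = tree.query(targets, k=k)
    idx = np.atleast_2d(idx)

    preds = np.full(targets.shape[0], NODATA_DEFAULT)
    kvar = np.zeros(targets.shape[0])
    failed = 0
    for c, target in enumerate(targets):
        neigh = pts[idx[c]]
        sol = kriging_weights(neigh, target, variogram)
        if sol is None:
            failed += 1
            continue
        w, mu = sol
        preds[c] = float(w @ z[idx[c]])
        g0 = variogram(np.linalg.norm(neigh - target, axis=1))
        kvar[c] = max(float(w @ g0 + mu), 0.0)
    if failed:
        log.warning("ordinary_kriging: %d singular cell(s) set to NODATA", failed)
    grid = ExposureGrid(
        year=target_grid.year,
        cell_size=target_grid.cell_size,
        origin=target_grid.origin,
        values=np.maximum(preds.reshape(lons.shape), 0.0),
        nodata=NODATA_DEFAULT,
    )
    # re-mark failures after the nonnegativity clamp
    grid.values[preds.reshape(lons.shape) == NODATA_DEFAULT] = NODATA_DEFAULT
    return KrigedSurface(
        grid=grid,
        variance=kvar.reshape(lons.shape),
        outcome=outcome,
        year=target_grid.year,
        failed_cells=failed,
    )
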