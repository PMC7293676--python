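"""Spatial weights, neighborhood means, and Global Moran's I.

Two weight schemes are provided, mirroring how areal studies typically use
them: binary queen contiguity (areas sharing any boundary point) for the
neighborhood mean, and inverse-distance weights for autocorrelation testing.
Inverse-distance weights are not row-standardized by default; a flag enables
it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

WEIGHT_KINDS = {"queen_binary", "inverse_distance", "custom"}
ASSUMPTIONS = {"normality", "randomization", "permutation"}


@dataclass
class SpatialWeights:
    """n x n nonnegative weight structure over ordered areal units."""

    ids: tuple[str, ...]
    W: np.ndarray
    kind: str = "custom"
    row_standardized: bool = False

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.ids)
        if self.W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {self.W.shape}")
        if self.kind not in WEIGHT_KINDS:
            raise ValueError(f"unknown weight kind {self.kind!r}")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal weights must be zero")
        if np.any(self.W < 0):
            raise ValueError("weights must be nonnegative")
        if self.S0 <= 0:
            raise ValueError("S0 = 0: all-island weight matrix rejected")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def S0(self) -> float:
        return float(self.W.sum())

    def row_standardize(self) -> "SpatialWeights":
        sums = self.W.sum(axis=1, keepdims=True)
        W = np.divide(self.W, sums, out=np.zeros_like(self.W), where=sums > 0)
        return SpatialWeights(self.ids, W, kind=self.kind, row_standardized=True)

    def to_triplet_frame(self) -> pd.DataFrame:
        ii, jj = np.nonzero(self.W)
        return pd.DataFrame(
            {
                "i_id": [self.ids[i] for i in ii],
                "j_id": [self.ids[j] for j in jj],
                "w": self.W[ii, jj],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_triplet_frame().to_csv(path, index=False, float_format="%.10g")


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    n: int
    assumption: str


def queen_weights(region) -> SpatialWeights:
    """Binary contiguity weights: w_ij = 1 iff i and j share a boundary point.

    Uses the region's precomputed adjacency relation.  Islands are permitted
    (logged); a region where every area is an island is rejected.
    """
    ids = tuple(a.area_id for a in region.areas)
    if len(ids) < 2:
        raise ValueError("need at least 2 areas")
    index = {aid: k for k, aid in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for aid, neighbors in region.adjacency.items():
        for bid in neighbors:
            W[index[aid], index[bid]] = 1.0
    if not np.allclose(W, W.T):
        raise ValueError("queen adjacency must be symmetric")
    islands = [ids[k] for k in range(len(ids)) if W[k].sum() == 0]
    if len(islands) == len(ids):
        raise ValueError("S0 = 0: every area is an island")
    if islands:
        log.warning("queen_weights: %d island area(s): %s", len(islands), islands)
    return SpatialWeights(ids, W, kind="queen_binary")


def inverse_distance_weights(
    centroids: Mapping[str, tuple[float, float]],
    power: float = 1.0,
    cutoff: float | None = None,
    row_standardize: bool = False,
    great_circle: bool = False,
) -> SpatialWeights:
    """w_ij = 1 / d_ij**power, optionally zeroed beyond ``cutoff``.

    Distances are planar Euclidean in degrees by default (appropriate for the
    synthetic lattice); ``great_circle=True`` switches to haversine km for
    real lon/lat data.
    """
    ids = tuple(centroids.keys())
    xy = np.array([centroids[i] for i in ids], dtype=float)
    if len(ids) < 2:
        raise ValueError("need at least 2 centroids")
    if great_circle:
        d = _haversine_matrix(xy)
    else:
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.hypot(diff[..., 0], diff[..., 1])
    off = ~np.eye(len(ids), dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        raise ValueError(
            f"coincident centroids: {ids[i]!r} and {ids[j]!r} (infinite weight)"
        )
    with np.errstate(divide="ignore"):
        W = 1.0 / d**power
    np.fill_diagonal(W, 0.0)
    if cutoff is not None:
        W[d > cutoff] = 0.0
    w = SpatialWeights(ids, W, kind="inverse_distance")
    return w.row_standardize() if row_standardize else w


def _haversine_matrix(lonlat: np.ndarray) -> np.ndarray:
    R = 6371.0088  # mean Earth radius, km
    lam = np.radians(lonlat[:, 0])
    phi = np.radians(lonlat[:, 1])
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2 * R * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def regional_mean(values: Mapping[str, float], region) -> dict[str, float]:
    """Unweighted mean of each area's contiguity neighbors' values.

    Islands map to NaN.  Every area in the region must be covered by
    ``values``.
    """
    missing = [a.area_id for a in region.areas if a.area_id not in values]
    if missing:
        raise ValueError(f"values missing for areas: {missing[:5]}")
    out: dict[str, float] = {}
    for area in region.areas:
        neigh = region.adjacency.get(area.area_id, ())
        if not neigh:
            out[area.area_id] = math.nan
        else:
            out[area.area_id] = float(np.mean([values[b] for b in neigh]))
    return out


# ---------------------------------------------------------------------------
# Global Moran's I


def _moran_statistic(xc: np.ndarray, W: np.ndarray, S0: float) -> float:
    n = xc.size
    num = float(xc @ W @ xc)
    den = float(xc @ xc)
    return (n / S0) * num / den


def morans_i(
    x: Sequence[float] | np.ndarray,
    weights: SpatialWeights,
    assumption: str = "randomization",
    permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with an analytic or permutation significance test.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    ``assumption`` selects the variance: the normality or randomization
    closed forms, or a Monte-Carlo permutation null (``permutations``
    relabelings drawn from ``seed``).
    """
    if assumption not in ASSUMPTIONS:
        raise ValueError(f"unknown assumption {assumption!r}")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n != weights.n:
        raise ValueError("x length must match weight matrix")
    if n < 4:
        raise ValueError("need n >= 4 areas")
    xc = x - x.mean()
    m2 = float(xc @ xc) / n
    if m2 == 0:
        raise ValueError("zero variance, Moran's I undefined")
    W = weights.W
    S0 = weights.S0
    I = _moran_statistic(xc, W, S0)
    EI = -1.0 / (n - 1)

    S1 = 0.5 * float(((W + W.T) ** 2).sum())
    rows = W.sum(axis=1)
    cols = W.sum(axis=0)
    S2 = float(((rows + cols) ** 2).sum())

    if assumption == "normality":
        var = (n * n * S1 - n * S2 + 3 * S0 * S0) / (S0 * S0 * (n * n - 1)) - EI * EI
        z = (I - EI) / math.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    elif assumption == "randomization":
        m4 = float((xc**4).mean())
        b2 = m4 / (m2 * m2)
        num = n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0) - b2 * (
            (n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * S0 * S0) - EI * EI
        z = (I - EI) / math.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    else:  # permutation
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(xc, (permutations, 1)), axis=1)
        sims = (n / S0) * ((perms @ W) * perms).sum(axis=1) / (n * m2)
        var = float(sims.var(ddof=1))
        z = (I - float(sims.mean())) / math.sqrt(var)
        extreme = int(np.sum(np.abs(sims - sims.mean()) >= abs(I - sims.mean())))
        p = min(1.0, (extreme + 1) / (permutations + 1))
    return MoranResult(
        I=float(I),
        expected=EI,
        variance=float(var),
        z=float(z),
        p_value=float(p),
        n=n,
        assumption=assumption,
    )


def moran_table(
    panel: pd.DataFrame,
    value_column: str,
    weights: SpatialWeights,
    assumption: str = "randomization",
) -> pd.DataFrame:
    """Per-year Moran results for one panel variable, as a tidy frame.

    Only areas present in a given year enter that year's test; the weight
    matrix is subset accordingly.
    """
    rows = []
    for year, grp in panel.groupby("year"):
        sub = grp.set_index("area_id")[value_column]
        keep = [k for k, aid in enumerate(weights.ids) if aid in sub.index]
        if len(keep) < 4:
            continue
        ids = tuple(weights.ids[k] for k in keep)
        Wsub = weights.W[np.ix_(keep, keep)]
        if Wsub.sum() == 0:
            continue
        w = SpatialWeights(ids, Wsub, kind="custom")
        res = morans_i(sub.loc[list(ids)].to_numpy(), w, assumption=assumption)
        rows.append(
            {
                "variable": value_column,
                "year": year,
                "I": res.I,
                "expected": res.expected,
                "variance": res.variance,
                "z": res.z,
                "p": res.p_value,
                "assumption": res.assumption,
            }
        )
    return pd.DataFrame(rows)
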