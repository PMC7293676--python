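"""Synthetic study regions, exposure surfaces, and outcome panels.

The generator emulates the statistical structure the downstream analysis
assumes without any external data:

* a rectangular lattice of square areal units with queen adjacency,
* yearly concentration surfaces = east-west linear gradient + a Gaussian
  random field with exponential covariance, persistent across years via an
  AR(1) in the field component,
* an unbalanced outcome panel whose yearly coverage follows a registry
  schedule (areas enter once and never exit), with rates produced by a
  linear model in the 9 local and 9 neighborhood-mean exposure lags.

Everything is deterministic given ``GeneratorConfig.seed``; independent
named substreams keep the region, fields, registry entry, and outcome noise
decoupled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from . import spatial
from .exposure import ExposureGrid, aggregate_panel

# substream spawn keys off the master seed
_STREAM_POPULATION = 0
_STREAM_FIELD = 1
_STREAM_REGISTRY = 2
_STREAM_MORTALITY = 3
_STREAM_MORBIDITY = 4

#: Yearly number of reporting areas used as the default unbalanced-coverage
#: schedule (counts for 2006..2014).
DEFAULT_REGISTRY_SCHEDULE: dict[int, int] = {
    2006: 34,
    2007: 38,
    2008: 41,
    2009: 72,
    2010: 145,
    2011: 177,
    2012: 193,
    2013: 255,
    2014: 339,
}


@dataclass(frozen=True)
class AreaUnit:
    """One areal unit: a simple closed polygon plus yearly populations."""

    area_id: str
    polygon: tuple[tuple[float, float], ...]
    centroid: tuple[float, float]
    population_by_year: dict[int, int]

    def __post_init__(self) -> None:
        if self.polygon[0] != self.polygon[-1]:
            raise ValueError(f"polygon of {self.area_id!r} must be closed")
        if any(p <= 0 for p in self.population_by_year.values()):
            raise ValueError(f"non-positive population in area {self.area_id!r}")


@dataclass(frozen=True)
class StudyRegion:
    areas: tuple[AreaUnit, ...]
    adjacency: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        ids = [a.area_id for a in self.areas]
        if len(set(ids)) != len(ids):
            raise ValueError("area_ids must be unique")
        for aid, neigh in self.adjacency.items():
            if aid in neigh:
                raise ValueError(f"adjacency must be irreflexive ({aid!r})")
            for bid in neigh:
                if aid not in self.adjacency.get(bid, frozenset()):
                    raise ValueError(f"adjacency must be symmetric ({aid!r}, {bid!r})")

    @property
    def area_ids(self) -> tuple[str, ...]:
        return tuple(a.area_id for a in self.areas)

    def area(self, area_id: str) -> AreaUnit:
        for a in self.areas:
            if a.area_id == area_id:
                return a
        raise KeyError(area_id)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic generator.

    ``beta_loc`` / ``lambda_reg`` are the 9 local / 9 neighborhood-mean lag
    coefficients of the outcome model (lag 0 first); ``alpha`` is the
    intercept on the rate-per-100,000 scale.  Default coefficient magnitudes
    are a calibration chosen so that pooled lag correlations land in the
    0.15-0.30 band with the local series dominating; they are not literature
    values.
    """

    n_rows: int = 18
    n_cols: int = 19
    exposure_years: tuple[int, int] = (1998, 2016)
    outcome_years: tuple[int, int] = (2006, 2014)
    beta_loc: tuple[float, ...] = (0.07,) * 9
    lambda_reg: tuple[float, ...] = (0.012,) * 9
    alpha: float = 20.0
    sigma_eps: float = 15.0
    morbidity_scale: float = 1.2
    field_mean: float = 35.0
    field_sill: float = 120.0
    field_range: float = 0.35
    field_gradient: float = 0.5  # ug/m3 per degree longitude, west -> east
    field_ar: float = 0.8
    field_floor: float = 0.5
    registry_schedule: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_REGISTRY_SCHEDULE)
    )
    area_size: float = 1.0  # degrees per lattice cell
    cells_per_area: int = 4  # exposure grid cells per area side
    origin: tuple[float, float] = (100.0, 20.0)
    population_range: tuple[int, int] = (100_000, 2_000_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta_loc) != 9 or len(self.lambda_reg) != 9:
            raise ValueError("coefficient vectors must have length 9")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("lattice must be at least 2x2 (adjacency degenerate)")
        counts = [self.registry_schedule[y] for y in sorted(self.registry_schedule)]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError("registry_schedule must be nondecreasing over years")
        if counts and max(counts) > self.n_rows * self.n_cols:
            raise ValueError("registry_schedule count exceeds number of areas")
        if not (0 <= self.field_ar < 1):
            raise ValueError("field_ar must be in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )

    @property
    def outcome_year_list(self) -> list[int]:
        return list(range(self.outcome_years[0], self.outcome_years[1] + 1))

    @property
    def exposure_year_list(self) -> list[int]:
        return list(range(self.exposure_years[0], self.exposure_years[1] + 1))


# ---------------------------------------------------------------------------
# Region


def generate_region(config: GeneratorConfig) -> StudyRegion:
    """Rectangular lattice of square areas with queen adjacency.

    Area ids are row-major, zero-padded, so lexicographic order equals
    generation order.  Populations are drawn once per area and held constant
    over the outcome years.
    """
    nr, nc = config.n_rows, config.n_cols
    if nr * nc < 4:
        raise ValueError("lattice must contain at least 4 areas")
    s = config.area_size
    x0, y0 = config.origin
    rng = config.rng(_STREAM_POPULATION)
    pops = rng.integers(*config.population_range, size=nr * nc)
    years = config.outcome_year_list
    width = len(str(nr * nc - 1))
    areas = []
    for r in range(nr):
        for c in range(nc):
            idx = r * nc + c
            xl, yb = x0 + c * s, y0 + r * s
            ring = (
                (xl, yb),
                (xl + s, yb),
                (xl + s, yb + s),
                (xl, yb + s),
                (xl, yb),
            )
            areas.append(
                AreaUnit(
                    area_id=f"a{idx:0{width}d}",
                    polygon=ring,
                    centroid=(xl + s / 2, yb + s / 2),
                    population_by_year={y: int(pops[idx]) for y in years},
                )
            )
    adjacency: dict[str, frozenset[str]] = {}
    for r in range(nr):
        for c in range(nc):
            neigh = set()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc:
                        neigh.add(areas[rr * nc + cc].area_id)
            adjacency[areas[r * nc + c].area_id] = frozenset(neigh)
    return StudyRegion(areas=tuple(areas), adjacency=adjacency)


# ---------------------------------------------------------------------------
# Exposure fields


def gaussian_random_field(
    n_rows: int,
    n_cols: int,
    spacing: float,
    sill: float,
    range_: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary zero-mean field with covariance C(h) = sill * exp(-h/range).

    Sampled by circulant embedding on a padded torus (FFT); tiny negative
    embedding eigenvalues are clipped to zero.
    """
    if sill < 0 or range_ <= 0 or spacing <= 0:
        raise ValueError("sill must be >= 0 and range/spacing > 0")
    if sill == 0:
        return np.zeros((n_rows, n_cols))
    M = 1 << int(np.ceil(np.log2(max(2 * n_rows, 8))))
    N = 1 << int(np.ceil(np.log2(max(2 * n_cols, 8))))
    dr = np.minimum(np.arange(M), M - np.arange(M)) * spacing
    dc = np.minimum(np.arange(N), N - np.arange(N)) * spacing
    h = np.hypot(dr[:, None], dc[None, :])
    cov = sill * np.exp(-h / range_)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    eps = rng.standard_normal((M, N)) + 1j * rng.standard_normal((M, N))
    f = np.fft.fft2(eps * np.sqrt(lam)) / np.sqrt(M * N)
    return np.ascontiguousarray(f.real[:n_rows, :n_cols])


def generate_exposure_fields(
    region: StudyRegion, config: GeneratorConfig
) -> dict[int, ExposureGrid]:
    """Yearly surfaces on a grid nested ``cells_per_area`` x per area.

    surface(year) = gradient + AR(1)-persistent Gaussian field, truncated
    below at ``field_floor``.
    """
    if config.field_range <= 0 or config.field_sill <= 0:
        raise ValueError("field_range and field_sill must be positive")
    nr = config.n_rows * config.cells_per_area
    nc = config.n_cols * config.cells_per_area
    spacing = config.area_size / config.cells_per_area
    x0, y0 = config.origin
    lon = x0 + (np.arange(nc) + 0.5) * spacing
    lon_mid = x0 + config.n_cols * config.area_size / 2
    gradient = config.field_mean + config.field_gradient * (lon - lon_mid)
    gradient = np.broadcast_to(gradient, (nr, nc))

    rng = config.rng(_STREAM_FIELD)
    rho = config.field_ar
    grids: dict[int, ExposureGrid] = {}
    fld = None
    for year in config.exposure_year_list:
        innov = gaussian_random_field(
            nr, nc, spacing, config.field_sill, config.field_range, rng
        )
        fld = innov if fld is None else rho * fld + np.sqrt(1 - rho * rho) * innov
        values = np.maximum(gradient + fld, config.field_floor)
        grids[year] = ExposureGrid(
            year=year, cell_size=spacing, origin=(x0, y0), values=values
        )
    return grids


# ---------------------------------------------------------------------------
# Outcomes


def registry_coverage(
    region: StudyRegion, config: GeneratorConfig
) -> dict[int, tuple[str, ...]]:
    """Which areas report in each outcome year.

    Entrants are drawn without replacement among not-yet-covered areas; once
    in, an area never exits, so coverage is nested across years.
    """
    rng = config.rng(_STREAM_REGISTRY)
    ids = list(region.area_ids)
    covered: list[str] = []
    out: dict[int, tuple[str, ...]] = {}
    for year in sorted(config.registry_schedule):
        target = config.registry_schedule[year]
        pool = [a for a in ids if a not in covered]
        n_new = target - len(covered)
        if n_new < 0:
            raise ValueError("registry_schedule must be nondecreasing")
        entrants = rng.choice(len(pool), size=n_new, replace=False) if n_new else []
        covered.extend(pool[k] for k in sorted(entrants))
        out[year] = tuple(sorted(covered))
    return out


def generate_outcomes(
    region: StudyRegion,
    exposure_panel: pd.DataFrame,
    config: GeneratorConfig,
    rate_floor: float = 0.01,
) -> pd.DataFrame:
    """Outcome panel from the linear lag model on local and neighborhood means.

    rate(t, i) = alpha + sum_k beta_loc[k] * loc_lag_k + sum_k
    lambda_reg[k] * reg_lag_k + eps, floored at ``rate_floor`` per 100,000.
    Morbidity uses the same structure scaled by ``morbidity_scale`` with an
    independent noise draw.
    """
    years_needed = range(
        config.outcome_years[0] - 8, config.outcome_years[1] + 1
    )
    have = set(exposure_panel["year"].unique())
    missing = sorted(set(years_needed) - have)
    if missing:
        raise ValueError(
            f"insufficient lag history: exposure panel missing years {missing}"
        )

    loc = exposure_panel.pivot(index="area_id", columns="year", values="mean_pm25")
    reg = pd.DataFrame(
        {
            year: spatial.regional_mean(loc[year].to_dict(), region)
            for year in loc.columns
        }
    )
    coverage = registry_coverage(region, config)
    rng_mort = config.rng(_STREAM_MORTALITY)
    rng_morb = config.rng(_STREAM_MORBIDITY)
    beta = np.asarray(config.beta_loc)
    lam = np.asarray(config.lambda_reg)

    records = []
    for year in config.outcome_year_list:
        for aid in coverage.get(year, ()):
            lag_years = [year - k for k in range(9)]
            loc_lags = loc.loc[aid, lag_years].to_numpy(dtype=float)
            reg_lags = reg.loc[aid, lag_years].to_numpy(dtype=float)
            signal = float(beta @ loc_lags + lam @ reg_lags)
            mort = config.alpha + signal + rng_mort.normal(0, config.sigma_eps)
            morb = config.morbidity_scale * (
                config.alpha + signal
            ) + rng_morb.normal(0, config.sigma_eps)
            records.append(
                (
                    aid,
                    year,
                    max(mort, rate_floor),
                    max(morb, rate_floor),
                    region.area(aid).population_by_year.get(year, 1),
                )
            )
    return pd.DataFrame(
        records,
        columns=["area_id", "year", "mortality_rate", "morbidity_rate", "population"],
    )


# ---------------------------------------------------------------------------
# Convenience + serialization


def simulate(config: GeneratorConfig) -> dict:
    """Run the full generator: region, grids, exposure panel, outcome panel."""
    region = generate_region(config)
    grids = generate_exposure_fields(region, config)
    exposure_panel = aggregate_panel(grids, region.areas)
    outcomes = generate_outcomes(region, exposure_panel, config)
    return {
        "region": region,
        "grids": grids,
        "exposure_panel": exposure_panel,
        "outcomes": outcomes,
    }


def region_to_geojson(region: StudyRegion) -> dict:
    features = []
    for a in region.areas:
        props: dict = {"area_id": a.area_id}
        for year, pop in sorted(a.population_by_year.items()):
            props[f"population_{year}"] = pop
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(p) for p in a.polygon]],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_region_geojson(region: StudyRegion, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(region_to_geojson(region), fh, indent=1, sort_keys=True)


def read_region_geojson(path: str | Path) -> StudyRegion:
    """Rebuild a region from GeoJSON; adjacency is recomputed geometrically."""
    import shapely
    from shapely.geometry import shape

    with open(path) as fh:
        fc = json.load(fh)
    areas = []
    for feat in fc["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        ring = tuple(tuple(p) for p in feat["geometry"]["coordinates"][0])
        pops = {
            int(k.split("_")[1]): int(v)
            for k, v in props.items()
            if k.startswith("population_")
        }
        areas.append(
            AreaUnit(
                area_id=props["area_id"],
                polygon=ring,
                centroid=(geom.centroid.x, geom.centroid.y),
                population_by_year=pops,
            )
        )
    polys = [shapely.geometry.Polygon(a.polygon) for a in areas]
    tree = shapely.STRtree(polys)
    adjacency: dict[str, frozenset[str]] = {}
    for i, poly in enumerate(polys):
        hits = tree.query(poly, predicate="intersects")
        adjacency[areas[i].area_id] = frozenset(
            areas[j].area_id for j in hits if j != i
        )
    return StudyRegion(areas=tuple(areas), adjacency=adjacency)
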