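"""Area-level exposure aggregation, registry filtering/merging, and threshold
classification.

Gridded concentration surfaces are reduced to per-area annual means by
averaging the grid-cell *centers* that fall inside each area polygon.
Outcome panels are tabular (pandas) with a fixed column contract:

* exposure panel: ``area_id, year, mean_pm25, n_cells``
* outcome panel:  ``area_id, year, mortality_rate, morbidity_rate, population``

Rates are carried per 100,000 throughout; event counts are reconstructed
only inside :func:`merge_areas`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

log = logging.getLogger(__name__)

NODATA_DEFAULT = -9999.0

#: Annual-mean guideline thresholds in ug/m3, ascending.  A concentration is
#: classified by every threshold it *strictly* exceeds.
WHO_THRESHOLDS: tuple[tuple[str, float], ...] = (
    ("AQG", 10.0),
    ("IT-3", 15.0),
    ("IT-2", 25.0),
    ("IT-1", 35.0),
)

EXPOSURE_PANEL_COLUMNS = ["area_id", "year", "mean_pm25", "n_cells"]
OUTCOME_PANEL_COLUMNS = [
    "area_id",
    "year",
    "mortality_rate",
    "morbidity_rate",
    "population",
]


class EmptyIntersectionError(ValueError):
    """No non-NODATA grid-cell center falls inside the area polygon."""


@dataclass
class ExposureGrid:
    """One year's gridded concentration surface.

    ``values[r, c]`` is the concentration at the cell center
    ``(origin_x + (c + 0.5) * cell_size, origin_y + (r + 0.5) * cell_size)``,
    i.e. row index increases northward from the lower-left corner.
    """

    year: int
    cell_size: float
    origin: tuple[float, float]  # lon/lat of the lower-left grid corner
    values: np.ndarray
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.values != self.nodata
        if np.any(self.values[valid] < 0):
            raise ValueError("negative concentration in grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) arrays of all cell centers, shape = grid shape."""
        nr, nc = self.values.shape
        x0, y0 = self.origin
        lons = x0 + (np.arange(nc) + 0.5) * self.cell_size
        lats = y0 + (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(lons, lats)

    def mask_valid(self) -> np.ndarray:
        return self.values != self.nodata


# ---------------------------------------------------------------------------
# ESRI ASCII grid / long-CSV I/O


def write_ascii_grid(grid: ExposureGrid, path: str | Path) -> None:
    """Write as ESRI ASCII raster (rows stored north to south)."""
    nr, nc = grid.values.shape
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {grid.origin[0]:.10g}\n"
        f"yllcorner {grid.origin[1]:.10g}\n"
        f"cellsize {grid.cell_size:.10g}\n"
        f"NODATA_value {grid.nodata:.10g}\n"
    )
    body = np.flipud(grid.values)  # file convention: first row is northmost
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6f")


def read_ascii_grid(path: str | Path, year: int = 0) -> ExposureGrid:
    with open(path) as fh:
        hdr: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)
    return ExposureGrid(
        year=year,
        cell_size=hdr["cellsize"],
        origin=(hdr["xllcorner"], hdr["yllcorner"]),
        values=np.flipud(body),
        nodata=hdr.get("nodata_value", NODATA_DEFAULT),
    )


def grid_to_long_frame(grid: ExposureGrid) -> pd.DataFrame:
    """Long format (lon, lat, year, pm25), NODATA cells omitted."""
    lons, lats = grid.cell_centers()
    m = grid.mask_valid()
    return pd.DataFrame(
        {
            "lon": lons[m],
            "lat": lats[m],
            "year": grid.year,
            "pm25": grid.values[m],
        }
    )


# ---------------------------------------------------------------------------
# Aggregation


def _area_polygon(area) -> Polygon:
    poly = Polygon(area.polygon)
    if not poly.is_valid:
        raise ValueError(f"invalid polygon for area {area.area_id!r}")
    return poly


def aggregate_grid_to_area(grid: ExposureGrid, area) -> tuple[float, int]:
    """Mean of non-NODATA cell centers covered by the area polygon.

    Returns ``(mean_pm25, n_cells)``.  Raises
    :class:`EmptyIntersectionError` when no valid cell contributes.
    """
    poly = _area_polygon(area)
    lons, lats = grid.cell_centers()
    # centers exactly on the boundary count for a single-area query; the
    # cross-area tie-break lives in grid_area_assignment
    covered = shapely.intersects_xy(poly, lons.ravel(), lats.ravel())
    member = covered.reshape(lons.shape) & grid.mask_valid()
    n = int(member.sum())
    if n == 0:
        raise EmptyIntersectionError(
            f"empty intersection: no valid grid cell inside area {area.area_id!r}"
        )
    return float(grid.values[member].mean()), n


def grid_area_assignment(grid: ExposureGrid, areas: Sequence) -> np.ndarray:
    """Assign every grid cell to at most one area.

    Returns an int array (grid shape) of indices into ``areas`` sorted by
    ``area_id``; ``-1`` marks unassigned cells.  A center lying on a shared
    boundary belongs to the covering area whose ``area_id`` is
    lexicographically smallest (deterministic tie-break).
    """
    order = np.argsort([a.area_id for a in areas])
    lons, lats = grid.cell_centers()
    flat_x, flat_y = lons.ravel(), lats.ravel()
    assign = np.full(flat_x.shape, -1, dtype=int)
    for idx in order:
        area = areas[idx]
        poly = _area_polygon(area)
        x0, y0, x1, y1 = poly.bounds
        cand = np.flatnonzero(
            (assign < 0)
            & (flat_x >= x0)
            & (flat_x <= x1)
            & (flat_y >= y0)
            & (flat_y <= y1)
        )
        if cand.size == 0:
            continue
        hit = shapely.intersects_xy(poly, flat_x[cand], flat_y[cand])
        assign[cand[hit]] = idx
    return assign.reshape(lons.shape)


def aggregate_panel(
    grids: Mapping[int, ExposureGrid],
    areas: Sequence,
    assignment: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aggregate a multi-year grid series to an exposure panel.

    The cell-to-area assignment is geometric only and therefore computed once
    and reused across years (all grids must share one geometry).
    """
    grids = dict(sorted(grids.items()))
    first = next(iter(grids.values()))
    if assignment is None:
        assignment = grid_area_assignment(first, areas)
    flat_assign = assignment.ravel()
    records = []
    for year, grid in grids.items():
        if grid.values.shape != first.values.shape:
            raise ValueError("all grids must share one geometry")
        vals = grid.values.ravel()
        valid = vals != grid.nodata
        for idx, area in enumerate(areas):
            sel = (flat_assign == idx) & valid
            n = int(sel.sum())
            if n == 0:
                raise EmptyIntersectionError(
                    f"empty intersection: no valid grid cell inside area "
                    f"{area.area_id!r} in year {year}"
                )
            records.append((area.area_id, year, float(vals[sel].mean()), n))
    return pd.DataFrame(records, columns=EXPOSURE_PANEL_COLUMNS)


# ---------------------------------------------------------------------------
# Threshold classification, merging, filtering


def classify_who(conc: float) -> tuple[str, ...]:
    """Return names of all guideline thresholds strictly exceeded, ascending."""
    if conc < 0:
        raise ValueError(f"negative concentration: {conc}")
    return tuple(name for name, thr in WHO_THRESHOLDS if conc > thr)


def merge_areas(records: Iterable[tuple[float, float]]) -> float:
    """Pool small areas: rate per 100,000 from total events / total population.

    ``records`` are ``(event_count, population)`` pairs.  This is the pooled
    rate, *not* the mean of rates.
    """
    records = list(records)
    if not records:
        raise ValueError("merge_areas requires at least one record")
    events = 0.0
    pop = 0.0
    for count, population in records:
        if population <= 0:
            raise ValueError("population must be positive")
        events += count
        pop += population
    return 100_000.0 * events / pop


def filter_zero_outcomes(panel: pd.DataFrame) -> pd.DataFrame:
    """Drop records whose mortality or morbidity rate is zero.

    A record survives iff both rates are strictly positive.  The number of
    dropped records is logged.
    """
    keep = (panel["mortality_rate"] > 0) & (panel["morbidity_rate"] > 0)
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_zero_outcomes: dropped %d of %d records", dropped, len(panel))
    return panel.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Panel validation + CSV round trips


def validate_exposure_panel(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(EXPOSURE_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"exposure panel missing columns: {sorted(missing)}")
    if (df["n_cells"] < 1).any():
        raise ValueError("n_cells must be >= 1")
    if (df["mean_pm25"] < 0).any():
        raise ValueError("mean_pm25 must be non-negative")
    return df


def validate_outcome_panel(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(OUTCOME_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"outcome panel missing columns: {sorted(missing)}")
    if (df["population"] <= 0).any():
        raise ValueError("population must be positive")
    if (df[["mortality_rate", "morbidity_rate"]] < 0).any().any():
        raise ValueError("rates must be non-negative")
    if df.duplicated(["area_id", "year"]).any():
        raise ValueError("(area_id, year) must be unique")
    return df


def read_outcome_panel(path: str | Path) -> pd.DataFrame:
    return validate_outcome_panel(pd.read_csv(path))


def write_outcome_panel(df: pd.DataFrame, path: str | Path) -> None:
    validate_outcome_panel(df)[OUTCOME_PANEL_COLUMNS].to_csv(
        path, index=False, float_format="%.10g"
    )


def read_exposure_panel(path: str | Path) -> pd.DataFrame:
    return validate_exposure_panel(pd.read_csv(path))


def write_exposure_panel(df: pd.DataFrame, path: str | Path) -> None:
    validate_exposure_panel(df)[EXPOSURE_PANEL_COLUMNS].to_csv(
        path, index=False, float_format="%.10g"
    )
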