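import numpy as np
import pytest

from spatlag import design as design_mod
from spatlag.cli import _regional_frame
from spatlag.synth import AreaUnit, GeneratorConfig, StudyRegion, simulate


def unit_square_area(area_id, col, row, size=1.0, pop=100_000, years=(2006,)):
    xl, yb = col * size, row * size
    ring = ((xl, yb), (xl + size, yb), (xl + size, yb + size), (xl, yb + size), (xl, yb))
    return AreaUnit(
        area_id=area_id,
        polygon=ring,
        centroid=(xl + size / 2, yb + size / 2),
        population_by_year={y: pop for y in years},
    )


def strip_region(n=3):
    """1 x n chain of unit squares (too small for the generator, built by hand)."""
    areas = tuple(unit_square_area(f"s{i}", i, 0) for i in range(n))
    adjacency = {}
    for i in range(n):
        neigh = set()
        if i > 0:
            neigh.add(f"s{i-1}")
        if i < n - 1:
            neigh.add(f"s{i+1}")
        adjacency[f"s{i}"] = frozenset(neigh)
    return StudyRegion(areas=areas, adjacency=adjacency)


def full_coverage_config(n=12, seed=0, **overrides):
    """Lattice where every area reports in every outcome year."""
    params = dict(
        n_rows=n,
        n_cols=n,
        seed=seed,
        registry_schedule={y: n * n for y in range(2006, 2015)},
    )
    params.update(overrides)
    return GeneratorConfig(**params)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulation at generator defaults (registry schedule of
    34..339 areas over 2006-2014)."""
    return simulate(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_lag_design(default_sim):
    regional = _regional_frame(default_sim["exposure_panel"], default_sim["region"])
    return design_mod.build_lag_design(
        default_sim["exposure_panel"], regional, default_sim["outcomes"]
    )


@pytest.fixture(scope="session")
def small_sim():
    """Fast 6x6 fully covered panel for protocol-level tests."""
    return simulate(full_coverage_config(n=6, seed=1))


@pytest.fixture(scope="session")
def small_lag_design(small_sim):
    regional = _regional_frame(small_sim["exposure_panel"], small_sim["region"])
    return design_mod.build_lag_design(
        small_sim["exposure_panel"], regional, small_sim["outcomes"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
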