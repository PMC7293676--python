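import numpy as np
import pandas as pd
import pytest

from spatlag.cli import _regional_frame
from spatlag.exposure import aggregate_panel
from spatlag.synth import (
    DEFAULT_REGISTRY_SCHEDULE,
    GeneratorConfig,
    gaussian_random_field,
    generate_exposure_fields,
    generate_outcomes,
    generate_region,
    read_region_geojson,
    registry_coverage,
    simulate,
    write_region_geojson,
)

from conftest import full_coverage_config


def tiny_config(**kw):
    params = dict(
        n_rows=2,
        n_cols=2,
        registry_schedule={y: 4 for y in range(2006, 2015)},
        seed=0,
    )
    params.update(kw)
    return GeneratorConfig(**params)


class TestGenerateRegion:
    def test_2x2_all_pairs_adjacent(self):
        region = generate_region(tiny_config())
        assert len(region.areas) == 4
        for aid in region.area_ids:
            assert region.adjacency[aid] == frozenset(set(region.area_ids) - {aid})

    def test_3x3_neighbor_counts(self):
        region = generate_region(tiny_config(n_rows=3, n_cols=3))
        degrees = sorted(len(v) for v in region.adjacency.values())
        # 4 corners with 3, 4 edges with 5, 1 center with 8
        assert degrees == [3, 3, 3, 3, 5, 5, 5, 5, 8]

    @pytest.mark.parametrize("shape", [(1, 3), (3, 1), (1, 1)])
    def test_degenerate_lattice_rejected(self, shape):
        with pytest.raises(ValueError, match="2x2"):
            tiny_config(n_rows=shape[0], n_cols=shape[1])

    def test_determinism(self):
        cfg = tiny_config(n_rows=4, n_cols=4, seed=7)
        r1, r2 = generate_region(cfg), generate_region(cfg)
        assert r1 == r2

    def test_polygons_closed_and_populations_positive(self):
        region = generate_region(tiny_config(n_rows=3, n_cols=4))
        for area in region.areas:
            assert area.polygon[0] == area.polygon[-1]
            assert all(p > 0 for p in area.population_by_year.values())


class TestExposureFields:
    def test_zero_sill_rejected_but_limit_is_gradient(self):
        cfg = tiny_config(n_rows=3, n_cols=3)
        region = generate_region(cfg)
        with pytest.raises(ValueError):
            generate_exposure_fields(region, tiny_config(n_rows=3, n_cols=3, field_sill=0.0))
        small = tiny_config(n_rows=3, n_cols=3, field_sill=1e-12)
        grids = generate_exposure_fields(region, small)
        grid = grids[2016]
        lons, _ = grid.cell_centers()
        lon_mid = small.origin[0] + small.n_cols * small.area_size / 2
        expected = small.field_mean + small.field_gradient * (lons - lon_mid)
        np.testing.assert_allclose(grid.values, expected, atol=1e-4)

    def test_negative_range_rejected(self):
        cfg = tiny_config(n_rows=3, n_cols=3, field_range=1.0)
        region = generate_region(cfg)
        bad = tiny_config(n_rows=3, n_cols=3)
        bad.field_range = -1.0
        with pytest.raises(ValueError):
            generate_exposure_fields(region, bad)

    def test_field_mean_monte_carlo(self):
        # zero gradient: surface mean ~ field_mean within 3 SE over replicates
        sill, mean = 16.0, 35.0
        means = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fld = gaussian_random_field(40, 40, 0.25, sill, 1.0, rng)
            means.append(float((mean + fld).mean()))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - mean) < 3 * se + 1e-9

    def test_field_marginal_variance(self):
        # circulant embedding must reproduce the configured sill
        sill = 25.0
        var = np.mean(
            [
                gaussian_random_field(
                    32, 32, 0.5, sill, 1.0, np.random.default_rng(s)
                ).var()
                for s in range(60)
            ]
        )
        assert abs(var - sill) / sill < 0.15

    def test_ar1_persistence(self):
        cfg = tiny_config(n_rows=4, n_cols=4, field_gradient=0.0, field_ar=0.8)
        region = generate_region(cfg)
        grids = generate_exposure_fields(region, cfg)
        years = sorted(grids)
        corrs = [
            np.corrcoef(grids[y].values.ravel(), grids[y + 1].values.ravel())[0, 1]
            for y in years[:-1]
        ]
        assert np.mean(corrs) > 0.5

    def test_determinism(self):
        cfg = tiny_config(n_rows=3, n_cols=3, seed=11)
        region = generate_region(cfg)
        g1 = generate_exposure_fields(region, cfg)
        g2 = generate_exposure_fields(region, cfg)
        for y in g1:
            np.testing.assert_array_equal(g1[y].values, g2[y].values)

    def test_floor_truncation(self):
        cfg = tiny_config(n_rows=3, n_cols=3, field_mean=0.0, field_sill=50.0)
        region = generate_region(cfg)
        grids = generate_exposure_fields(region, cfg)
        assert all((g.values >= 0.5).all() for g in grids.values())


class TestOutcomes:
    def _panel(self, cfg):
        region = generate_region(cfg)
        grids = generate_exposure_fields(region, cfg)
        return region, aggregate_panel(grids, region.areas)

    def test_constant_model(self):
        cfg = full_coverage_config(
            n=3, sigma_eps=0.0, beta_loc=(0.0,) * 9, lambda_reg=(0.0,) * 9,
            alpha=40.0, morbidity_scale=1.0,
        )
        region, panel = self._panel(cfg)
        out = generate_outcomes(region, panel, cfg)
        assert (out["mortality_rate"] == 40.0).all()
        assert (out["morbidity_rate"] == 40.0).all()

    def test_registry_schedule_defaults(self, default_sim):
        counts = default_sim["outcomes"].groupby("year").size()
        assert counts.loc[2006] == 34
        assert counts.loc[2014] == 339
        assert counts.to_list() == [
            DEFAULT_REGISTRY_SCHEDULE[y] for y in sorted(DEFAULT_REGISTRY_SCHEDULE)
        ]

    def test_identity_mapping_loc_lag0(self):
        cfg = full_coverage_config(
            n=3, sigma_eps=0.0, beta_loc=(1.0,) + (0.0,) * 8,
            lambda_reg=(0.0,) * 9, alpha=5.0, morbidity_scale=1.0,
        )
        region, panel = self._panel(cfg)
        out = generate_outcomes(region, panel, cfg)
        merged = out.merge(panel, on=["area_id", "year"])
        np.testing.assert_allclose(
            merged["mortality_rate"] - cfg.alpha, merged["mean_pm25"], rtol=1e-12
        )

    def test_insufficient_lag_history_names_years(self):
        cfg = full_coverage_config(n=3, exposure_years=(2001, 2016))
        region, panel = self._panel(cfg)
        with pytest.raises(ValueError, match=r"1998.*1999.*2000"):
            generate_outcomes(region, panel, cfg)

    def test_coverage_monotone(self):
        cfg = GeneratorConfig(n_rows=5, n_cols=5, seed=3, registry_schedule={
            2006: 3, 2007: 5, 2008: 9, 2009: 12, 2010: 15,
            2011: 18, 2012: 20, 2013: 23, 2014: 25,
        })
        region = generate_region(cfg)
        cov = registry_coverage(region, cfg)
        years = sorted(cov)
        for a, b in zip(years, years[1:]):
            assert set(cov[a]) <= set(cov[b])

    def test_rate_floor(self):
        cfg = full_coverage_config(
            n=3, sigma_eps=0.0, beta_loc=(0.0,) * 9, lambda_reg=(0.0,) * 9,
            alpha=-50.0, morbidity_scale=1.0,
        )
        region, panel = self._panel(cfg)
        out = generate_outcomes(region, panel, cfg)
        assert (out["mortality_rate"] == 0.01).all()

    def test_full_determinism(self):
        cfg = full_coverage_config(n=4, seed=9)
        s1, s2 = simulate(cfg), simulate(cfg)
        pd.testing.assert_frame_equal(s1["outcomes"], s2["outcomes"])
        pd.testing.assert_frame_equal(s1["exposure_panel"], s2["exposure_panel"])


class TestConfigValidation:
    def test_coefficient_length(self):
        with pytest.raises(ValueError, match="length 9"):
            tiny_config(beta_loc=(0.1,) * 8)

    def test_negative_noise(self):
        with pytest.raises(ValueError, match="sigma_eps"):
            tiny_config(sigma_eps=-1.0)

    def test_schedule_decreasing_rejected(self):
        sched = {2006: 4, 2007: 3, 2008: 4, 2009: 4, 2010: 4,
                 2011: 4, 2012: 4, 2013: 4, 2014: 4}
        with pytest.raises(ValueError, match="nondecreasing"):
            tiny_config(registry_schedule=sched)

    def test_schedule_exceeding_area_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            tiny_config(registry_schedule={2006: 5})


def test_geojson_round_trip(tmp_path):
    cfg = full_coverage_config(n=3, seed=2)
    region = generate_region(cfg)
    path = tmp_path / "areas.geojson"
    write_region_geojson(region, path)
    back = read_region_geojson(path)
    assert back.area_ids == region.area_ids
    assert back.adjacency == region.adjacency
    for a, b in zip(back.areas, region.areas):
        assert a.population_by_year == b.population_by_year
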