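"""Regional climatologies, per-pixel atlases and eutrophication bands."""

import json

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from bloomatlas.atlas import (
    RegionSpec,
    build_atlas,
    classify_eutrophication,
    load_reference_table,
    load_regions,
    regional_climatology,
    summarize_regions,
)
from bloomatlas.calendar import composite_index_series
from bloomatlas.climatology import build_weekly_climatology
from bloomatlas.phenology import DetectorConfig, detect_growth_period
from bloomatlas.synthetic import BloomTruth, generate_daily_field


WHOLE_GRID = RegionSpec("box", 22.9, 24.1, 36.9, 38.1)


class TestEutrophication:
    @pytest.mark.parametrize("value, status", [
        (4.744, "bad"),      # hypereutrophic enclosed gulf
        (2.373, "bad"),
        (1.117, "poor"),
        (0.614, "poor"),
        (0.516, "moderate"),
        (0.394, "good"),
        (0.159, "good"),
        (0.089, "high"),
        (0.075, "high"),
    ])
    def test_reference_values(self, value, status):
        assert classify_eutrophication(value) == status

    @pytest.mark.parametrize("value, status", [
        (2.21, "poor"),      # boundaries belong to the better-status band
        (0.6, "moderate"),
        (0.4, "good"),
        (0.1, "high"),
        (0.0, "high"),
    ])
    def test_exact_boundaries(self, value, status):
        assert classify_eutrophication(value) == status

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_eutrophication(-0.1)


class TestRegionalClimatology:
    def test_homogeneous_field_equals_single_pixel(self, clean_field):
        clim_region = regional_climatology(clean_field, WHOLE_GRID)
        clim_pixel = build_weekly_climatology(
            clean_field.isel(lat=0, lon=0).to_series())
        np.testing.assert_allclose(clim_region.values, clim_pixel.values,
                                   rtol=1e-12)

    def test_two_pixel_region_averages(self):
        times = pd.date_range("2005-08-01", "2006-07-31", freq="D")
        vals = np.empty((len(times), 1, 2))
        vals[:, 0, 0] = 0.1
        vals[:, 0, 1] = 0.3
        field = xr.DataArray(vals, dims=("time", "lat", "lon"),
                             coords={"time": times, "lat": [37.0],
                                     "lon": [23.0, 23.5]})
        clim = regional_climatology(field, RegionSpec("r", 22, 24, 36, 38))
        assert np.allclose(clim.values, 0.2)

    def test_gappy_field_matches_mask_aware_oracle(self, rng):
        truth = BloomTruth(noise_cv=0.3, gap_fraction=0.4, n_years=3, seed=13)
        field, _ = generate_daily_field(truth, grid_shape=(3, 3))
        clim = regional_climatology(field, WHOLE_GRID)
        # oracle: per-date nanmean over pixels, then per-composite means
        daily = np.nanmean(field.values.reshape(field.sizes["time"], -1), axis=1)
        bins = composite_index_series(field["time"].values)
        expected = np.array([np.nanmean(daily[bins == b]) for b in range(1, 53)])
        np.testing.assert_allclose(clim.values, expected, rtol=1e-12)

    def test_empty_intersection_rejected(self, clean_field):
        with pytest.raises(ValueError):
            regional_climatology(clean_field, RegionSpec("off", 0, 1, 0, 1))


class TestAtlas:
    def test_uniform_field_gives_identical_metrics(self, clean_field):
        ds = build_atlas(clean_field, DetectorConfig(smoothing_sigma=0.0))
        assert int(ds["bloom_found"].sum()) == ds["bloom_found"].size
        for layer in ("initiation", "peak", "termination", "duration_days"):
            vals = ds[layer].values
            assert np.all(vals == vals[0, 0])

    def test_shifted_bloom_shifts_initiation(self):
        t_west = BloomTruth(baseline_chl=0.05, bloom_amplitude=0.5,
                            bloom_center_bin=26, bloom_width_bins=4,
                            noise_cv=0, gap_fraction=0, n_years=2, seed=0)
        t_east = BloomTruth(baseline_chl=0.05, bloom_amplitude=0.5,
                            bloom_center_bin=30, bloom_width_bins=4,
                            noise_cv=0, gap_fraction=0, n_years=2, seed=0)
        west, _ = generate_daily_field(t_west, grid_shape=(2, 2))
        east, _ = generate_daily_field(t_east, grid_shape=(2, 2),
                                       lon_range=(25.0, 26.0))
        field = xr.concat([west, east], dim="lon")
        ds = build_atlas(field, DetectorConfig(smoothing_sigma=0.0))
        init = ds["initiation"].values
        assert np.all(init[:, 2:] - init[:, :2] == 4)

    def test_constant_field_flags_no_bloom(self):
        times = pd.date_range("2005-08-01", "2007-07-31", freq="D")
        field = xr.DataArray(np.full((len(times), 2, 2), 0.2),
                             dims=("time", "lat", "lon"),
                             coords={"time": times, "lat": [37, 37.5],
                                     "lon": [23, 23.5]})
        ds = build_atlas(field)
        assert int(ds["bloom_found"].sum()) == 0
        assert np.isnan(ds["initiation"].values).all()

    def test_atlas_pixel_equals_one_pixel_region(self, clean_field):
        cfg = DetectorConfig(smoothing_sigma=0.0)
        ds = build_atlas(clean_field, cfg)
        lon = float(clean_field["lon"].values[1])
        lat = float(clean_field["lat"].values[2])
        eps = 1e-6
        region = RegionSpec("pix", lon - eps, lon + eps, lat - eps, lat + eps)
        row = summarize_regions(clean_field, [region], cfg).iloc[0]
        assert row["initiation_bin"] == ds["initiation"].values[2, 1]
        assert row["termination_bin"] == ds["termination"].values[2, 1]
        assert row["duration_days"] == ds["duration_days"].values[2, 1]


class TestSummarizeRegions:
    def test_synthetic_region_duration_from_truth(self):
        truth = BloomTruth(baseline_chl=0.05, bloom_amplitude=0.5,
                           bloom_center_bin=28, bloom_width_bins=5,
                           noise_cv=0, gap_fraction=0, n_years=2, seed=1)
        field, _ = generate_daily_field(truth, grid_shape=(3, 3))
        cfg = DetectorConfig(smoothing_sigma=0.0)
        table = summarize_regions(field, [WHOLE_GRID], cfg)
        row = table.iloc[0]
        from bloomatlas.phenology import bloom_threshold
        from bloomatlas.synthetic import generate_mean_cycle
        clim = generate_mean_cycle(truth)
        m = detect_growth_period(clim, cfg)
        assert row["duration_days"] == m.duration_days
        assert row["duration_days"] % 7 == 0

    def test_week_labels_render_reference_convention(self):
        truth = BloomTruth(baseline_chl=0.05, bloom_amplitude=0.5,
                           bloom_center_bin=28, bloom_width_bins=6,
                           noise_cv=0, gap_fraction=0, n_years=1, seed=1)
        field, _ = generate_daily_field(truth, grid_shape=(1, 1))
        cfg = DetectorConfig(smoothing_sigma=0.0)
        table = summarize_regions(field, [WHOLE_GRID], cfg)
        row = table.iloc[0]
        from bloomatlas.calendar import render_week_label
        assert row["initiation"] == render_week_label(row["initiation_bin"],
                                                      "onset")
        assert row["termination"] == render_week_label(row["termination_bin"],
                                                       "end")

    def test_bins_13_42_render_as_late_october_to_late_may(self):
        from bloomatlas.calendar import render_week_label
        from bloomatlas.phenology import duration_days
        assert render_week_label(13, "onset") == "24–30 Oct"
        assert render_week_label(42, "end") == "21–27 May"
        assert duration_days(13, 42) == 210

    def test_no_bloom_region_yields_flagged_row(self):
        times = pd.date_range("2005-08-01", "2006-07-31", freq="D")
        field = xr.DataArray(np.full((len(times), 2, 2), 0.2),
                             dims=("time", "lat", "lon"),
                             coords={"time": times, "lat": [37, 37.5],
                                     "lon": [23, 23.5]})
        table = summarize_regions(field, [RegionSpec("flat", 22, 24, 36, 38)])
        row = table.iloc[0]
        assert not row["bloom_found"]
        assert "duration_days" not in table.columns or pd.isna(
            row.get("duration_days"))

    def test_empty_region_list_rejected(self, clean_field):
        with pytest.raises(ValueError):
            summarize_regions(clean_field, [])


class TestRegionIO:
    def test_yaml_regions(self, tmp_path):
        p = tmp_path / "regions.yaml"
        p.write_text("- {name: A, lon_min: 22, lon_max: 23, "
                     "lat_min: 37, lat_max: 38, kind: open_sea}\n")
        (r,) = load_regions(p)
        assert r.name == "A" and r.kind == "open_sea"

    def test_geojson_rectangles(self, tmp_path):
        gj = {"type": "FeatureCollection", "features": [{
            "type": "Feature",
            "properties": {"name": "B", "kind": "coastal"},
            "geometry": {"type": "Polygon", "coordinates": [[
                [22, 37], [23, 37], [23, 38], [22, 38], [22, 37]]]},
        }]}
        p = tmp_path / "regions.geojson"
        p.write_text(json.dumps(gj))
        (r,) = load_regions(p)
        assert (r.lon_min, r.lon_max, r.lat_min, r.lat_max) == (22, 23, 37, 38)

    def test_degenerate_rectangle_rejected(self):
        with pytest.raises(ValueError):
            RegionSpec("bad", 23, 22, 37, 38)


def test_reference_table_loads_with_parsed_bins():
    df = load_reference_table()
    assert len(df) == 20
    assert df["kind"].value_counts().to_dict() == {"coastal": 12, "open_sea": 8}
    assert df["initiation_bin"].between(1, 52).all()
    assert df["termination_bin"].between(1, 52).all()
    assert (df["duration_days"] % 7 == 0).all()
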