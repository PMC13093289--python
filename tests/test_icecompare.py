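"""Projection, centroid/buffer sampling, ice extraction, crossing windows."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from postglacial.icecompare import (
    MONTHS,
    EventTimeline,
    HerdLocations,
    IceField,
    IceSeries,
    LaeaProjection,
    centroid_and_buffer,
    crossing_window,
    extract_ice_series,
    nearest_slice,
    overlay_events,
    population_centroid,
)
from postglacial.synthdata import IceFieldSpec, SyntheticSpec, make_ice_field


@pytest.fixture
def proj():
    return LaeaProjection(lon_0=90.0, lat_0=90.0)


def herds_from(rows):
    return HerdLocations(pd.DataFrame(rows, columns=["herd", "population", "lon", "lat"]))


class TestProjection:
    def test_round_trip(self, proj):
        lon = np.array([0.0, 45.0, 90.0, -120.0])
        lat = np.array([50.0, 70.0, 85.0, 60.0])
        x, y = proj.forward(lon, lat)
        lon2, lat2 = proj.inverse(x, y)
        assert np.allclose(((lon2 - lon + 180) % 360) - 180, 0.0, atol=1e-9)
        assert np.allclose(lat2, lat, atol=1e-9)

    def test_pole_maps_to_origin(self, proj):
        x, y = proj.forward(33.0, 90.0)
        assert abs(x) < 1e-9 and abs(y) < 1e-9

    def test_equal_area_near_center(self, proj):
        # a small 1-degree cell at 80N: projected area within 1% of spherical area
        R = proj.radius_km
        lat0, dlat, dlon = 80.0, 0.5, 0.5
        corners = [(90.0 - dlon, lat0 - dlat), (90.0 + dlon, lat0 - dlat),
                   (90.0 + dlon, lat0 + dlat), (90.0 - dlon, lat0 + dlat)]
        xy = np.array([proj.forward(lo, la) for lo, la in corners])
        # shoelace area of projected quadrilateral
        x, y = xy[:, 0], xy[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
        sphere = (
            R**2 * np.radians(2 * dlon)
            * (np.sin(np.radians(lat0 + dlat)) - np.sin(np.radians(lat0 - dlat)))
        )
        assert area == pytest.approx(sphere, rel=0.01)


class TestCentroids:
    def test_single_herd_population(self, proj):
        herds = herds_from([("h1", "A", 30.0, 75.0)])
        cx, cy = population_centroid(herds, "A", proj)
        ex, ey = proj.forward(30.0, 75.0)
        assert (cx, cy) == pytest.approx((ex, ey))

    def test_event_centroid_is_midpoint(self, proj):
        herds = herds_from([("h1", "A", 10.0, 80.0), ("h2", "B", 50.0, 80.0)])
        pts = centroid_and_buffer(herds, ["A", "B"], proj, buffer_km=1e-9,
                                  n_points=5, seed=0)
        ca = np.array(population_centroid(herds, "A", proj))
        cb = np.array(population_centroid(herds, "B", proj))
        assert np.allclose(pts.mean(axis=0), (ca + cb) / 2, atol=1e-6)

    def test_missing_population_errors(self, proj):
        herds = herds_from([("h1", "A", 10.0, 80.0)])
        with pytest.raises(ValueError, match="no herds"):
            centroid_and_buffer(herds, ["A", "B"], proj)

    def test_uniform_disc_sampling_law(self, proj):
        herds = herds_from([("h1", "A", 10.0, 80.0), ("h2", "B", 20.0, 80.0)])
        R = 100.0
        pts = centroid_and_buffer(herds, ["A", "B"], proj, buffer_km=R,
                                  n_points=10_000, seed=1)
        center = pts.mean(axis=0)
        ca = np.array(population_centroid(herds, "A", proj))
        cb = np.array(population_centroid(herds, "B", proj))
        r = np.hypot(*(pts - (ca + cb) / 2).T)
        assert np.all(r <= R + 1e-9)
        # radial CDF of a uniform disc is (r/R)^2
        assert kstest(r, lambda x: (x / R) ** 2).pvalue > 0.01


def uniform_field(value=0.8, n=30, land_cols=0):
    spec = SyntheticSpec(
        seed=0,
        ice=IceFieldSpec(nx=n, ny=n, base=value, trend_per_ka=0.0,
                         seasonal_amplitude=0.0, gradient_per_km=0.0,
                         noise_sd=0.0, t_start_ka=3.0, land_cols=land_cols),
    )
    return make_ice_field(spec)


class TestExtraction:
    def test_uniform_field_mean_invariant_to_radius(self):
        field = uniform_field(0.8)
        pts = np.array([[0.0, 0.0]])
        for radius in (100.0, 300.0, 600.0):
            s = extract_ice_series(field, pts, radius)
            assert np.allclose(s.mean.to_numpy(dtype=float), 0.8)
            assert np.allclose(s.sd.to_numpy(dtype=float), 0.0)

    def test_matches_brute_force_enumeration(self):
        # gradient + noise field; oracle enumerates every cell per point
        spec = SyntheticSpec(
            seed=4,
            ice=IceFieldSpec(nx=40, ny=40, base=0.5, trend_per_ka=0.01,
                             seasonal_amplitude=0.2, gradient_per_km=3e-4,
                             noise_sd=0.05, t_start_ka=4.0, land_cols=5),
        )
        field = make_ice_field(spec)
        pts = np.array([[50.0, -80.0], [-200.0, 120.0]])
        radius = 250.0
        series = extract_ice_series(field, pts, radius)

        ds = field.ds
        xs, ys = ds["x"].values, ds["y"].values
        gx, gy = np.meshgrid(xs, ys)
        for ti, t in enumerate(ds["time_ka"].values):
            land = ds["land_mask"].values[ti]
            for mi, mname in enumerate(MONTHS):
                grid = ds["sic"].values[ti, mi]
                means, sds = [], []
                for px, py in pts:
                    sel = ((gx - px) ** 2 + (gy - py) ** 2 <= radius**2) & (land == 0)
                    means.append(grid[sel].mean())
                    sds.append(grid[sel].std())
                assert series.mean.loc[t, mname] == pytest.approx(np.mean(means))
                assert series.sd.loc[t, mname] == pytest.approx(np.mean(sds))

    def test_all_land_disc_flagged_missing(self):
        field = uniform_field(0.8, n=30, land_cols=30)
        s = extract_ice_series(field, np.array([[0.0, 0.0]]), 100.0)
        assert s.mean.isna().all().all()
        assert len(s.flags["no_ocean_cells"]) == len(field.times_ka)

    def test_radius_must_exceed_cell_size(self):
        field = uniform_field()
        with pytest.raises(ValueError, match="exceed cell size"):
            extract_ice_series(field, np.array([[0.0, 0.0]]), 10.0)

    def test_seed_invariance_for_smooth_fields(self):
        from postglacial.icecompare import centroid_and_buffer as cab

        field = uniform_field(0.6)
        herds = herds_from([("h1", "A", 0.0, 89.0), ("h2", "B", 10.0, 89.0)])
        proj = field.projection
        vals = []
        for seed in (1, 2):
            pts = cab(herds, ["A", "B"], proj, buffer_km=100, n_points=50, seed=seed)
            vals.append(extract_ice_series(field, pts, 200.0).mean.iloc[0]["annual"])
        assert vals[0] == pytest.approx(vals[1], abs=1e-9)  # sd over points is 0


class TestCrossingWindow:
    def test_all_months_open(self):
        field = uniform_field(0.9)
        s = extract_ice_series(field, np.array([[0.0, 0.0]]), 100.0)
        w = crossing_window(s, threshold=0.70)
        assert w.all(axis=None)

    def test_seasonal_sinusoid_matches_closed_form(self):
        # sic(m) = 0.7 + 0.2 cos(2 pi (m - peak)/12), peak January:
        # below 0.70 exactly when cos < 0, i.e. months 4..10 (May..Nov edge)
        amp, base, peak = 0.2, 0.70, 1
        spec = SyntheticSpec(
            seed=0,
            ice=IceFieldSpec(nx=20, ny=20, base=base, trend_per_ka=0.0,
                             seasonal_amplitude=amp, peak_month=peak,
                             gradient_per_km=0.0, noise_sd=0.0, t_start_ka=2.0),
        )
        field = make_ice_field(spec)
        s = extract_ice_series(field, np.array([[0.0, 0.0]]), 100.0)
        w = crossing_window(s, threshold=0.70)
        closed_form = {
            m: base + amp * np.cos(2 * np.pi * (i - (peak - 1)) / 12.0) >= 0.70
            for i, m in enumerate(MONTHS)
        }
        for m in MONTHS:
            assert bool(w.iloc[0][m]) == closed_form[m], m
        # the closed months form the contiguous warm-season block:
        # cos is exactly 0 in Apr and Oct (0.70 = threshold, open), strictly
        # negative May..Sep (closed)
        closed = [m for m in MONTHS if not closed_form[m]]
        assert closed == ["May", "Jun", "Jul", "Aug", "Sep"]


class TestOverlay:
    def test_nearest_slice_rules(self):
        slices = np.arange(0.0, 25.0)
        assert nearest_slice(10.7, slices) == 11.0
        assert nearest_slice(10.5, slices) == 11.0  # tie toward older
        assert nearest_slice(10.4, slices) == 10.0
        assert nearest_slice(30.0, slices) == 24.0  # clamped
        # CI [7.4, 13.7] spans slices 7..14
        assert nearest_slice(7.4, slices) == 7.0
        assert nearest_slice(13.7, slices) == 14.0

    def test_overlay_table(self):
        field = uniform_field(0.85, n=30)
        s = extract_ice_series(field, np.array([[0.0, 0.0]]), 100.0)
        tl = EventTimeline(pd.DataFrame([
            {"event": "split", "kind": "divergence", "median_ka": 1.5,
             "ci_low_ka": 0.4, "ci_high_ka": 2.6},
        ]))
        out = overlay_events(tl, s)
        assert out.loc[0, "slice_ka"] == 2.0  # 1.5 ties toward older
        assert out.loc[0, "ci_slice_low_ka"] == 0.0
        assert out.loc[0, "ci_slice_high_ka"] == 3.0
        assert out.loc[0, "annual_mean"] == pytest.approx(0.85)
        assert out.loc[0, "open_months"].count(",") == 11  # all 12 open

    def test_invalid_timeline_rejected(self):
        with pytest.raises(ValueError, match="bracket"):
            EventTimeline(pd.DataFrame([
                {"event": "e", "kind": "divergence", "median_ka": 5.0,
                 "ci_low_ka": 6.0, "ci_high_ka": 7.0},
            ]))

    def test_plot_overlay_runs(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        field = uniform_field(0.85, n=30)
        s = extract_ice_series(field, np.array([[0.0, 0.0]]), 100.0)
        tl = EventTimeline(pd.DataFrame([
            {"event": "split", "kind": "divergence", "median_ka": 1.5,
             "ci_low_ka": 0.4, "ci_high_ka": 2.6},
        ]))
        from postglacial.icecompare import plot_overlay

        ax = plot_overlay(tl, s, months=["Mar", "Sep"])
        ax.figure.savefig(tmp_path / "overlay.png")


class TestNetcdf:
    def test_round_trip_bit_exact(self, tmp_path):
        field = uniform_field(0.42, n=12)
        path = tmp_path / "ice.nc"
        field.to_netcdf(path)
        again = IceField.from_netcdf(path)
        assert np.array_equal(again.ds["sic"].values, field.ds["sic"].values)
        assert np.array_equal(again.ds["land_mask"].values,
                              field.ds["land_mask"].values)
        assert again.projection == field.projection

    def test_out_of_range_concentration_rejected(self):
        field = uniform_field(0.5, n=12)
        ds = field.ds.copy(deep=True)
        ds["sic"][0, 0, 0, 0] = 1.5
        with pytest.raises(ValueError, match="outside"):
            IceField(ds, field.projection)
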