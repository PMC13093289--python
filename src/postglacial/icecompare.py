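"""Paleo sea-ice extraction around demographic event centroids.

Gridded monthly sea-ice concentration snapshots (1 ka steps) are held in an
xarray Dataset on a Lambert azimuthal equal-area grid (spherical formulas,
configurable central meridian, pole-centred — the polar equal-area setup
used for Arctic work).  For each demographic event the geographic position
is the midpoint of the participating populations' herd centroids; to avoid
anchoring on an arbitrary centroid, concentration is averaged over random
points sampled uniformly in a disc around it (default 100 points within
100 km), each point pulling in all non-land cells whose centers lie within
an extraction radius.  Crossing windows are the calendar months with mean
concentration at or above a threshold (default 70%, the minimum cover for
Rangifer sea-ice crossings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0
MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
          "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


# --------------------------------------------------------------------------
# Lambert azimuthal equal-area projection (spherical, pole-centred)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LaeaProjection:
    """Lambert azimuthal equal-area projection on the sphere.

    ``lon_0``/``lat_0`` give the projection center (degrees); coordinates
    are in km.  Equal-area, so cell areas are preserved — the property the
    extraction radius logic relies on.
    """

    lon_0: float = 0.0
    lat_0: float = 90.0
    radius_km: float = EARTH_RADIUS_KM

    def forward(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        lon0 = np.radians(self.lon_0)
        lat0 = np.radians(self.lat_0)
        dl = lon - lon0
        c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dl)
        c = np.clip(c, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.sqrt(2.0 / (1.0 + c))
        k = np.where(np.isclose(c, -1.0), 0.0, k)  # antipode, undefined
        x = self.radius_km * k * np.cos(lat) * np.sin(dl)
        y = self.radius_km * k * (
            np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dl)
        )
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.radius_km
        y = np.asarray(y, dtype=float) / self.radius_km
        lon0 = np.radians(self.lon_0)
        lat0 = np.radians(self.lat_0)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            lat = np.arcsin(
                np.cos(c) * np.sin(lat0) + y * np.sin(c) * np.cos(lat0) / rho
            )
            lon = lon0 + np.arctan2(
                x * np.sin(c),
                rho * np.cos(lat0) * np.cos(c) - y * np.sin(lat0) * np.sin(c),
            )
        lat = np.where(rho == 0, lat0, lat)
        lon = np.where(rho == 0, lon0, lon)
        return np.degrees(lon), np.degrees(lat)


# --------------------------------------------------------------------------
# ice fields
# --------------------------------------------------------------------------


@dataclass
class IceField:
    """Monthly sea-ice concentration snapshots on an equal-area grid.

    Wraps an xarray Dataset with dims (time_ka, month, y, x), variables
    ``sic`` (fraction in [0, 1]) and ``land_mask`` (time_ka, y, x; 1 = land),
    plus the projection used to build the grid.  ``x``/``y`` coordinates are
    cell-center positions in km.
    """

    ds: xr.Dataset
    projection: LaeaProjection = field(default_factory=LaeaProjection)

    def __post_init__(self) -> None:
        for var in ("sic", "land_mask"):
            if var not in self.ds:
                raise ValueError(f"ice field missing variable {var!r}")
        sic = self.ds["sic"]
        ocean = np.broadcast_to(
            self.ds["land_mask"].values[:, None, :, :] == 0, sic.shape
        )
        vals = sic.values[ocean]
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
            raise ValueError("sea-ice concentration outside [0, 1] over ocean")

    @property
    def times_ka(self) -> np.ndarray:
        return self.ds["time_ka"].values

    def annual_mean(self) -> xr.DataArray:
        return self.ds["sic"].mean("month")

    def to_netcdf(self, path) -> None:
        ds = self.ds.copy()
        ds.attrs.update(
            projection="laea_spherical",
            proj_lon_0=self.projection.lon_0,
            proj_lat_0=self.projection.lat_0,
            Conventions="CF-1.8-like",
        )
        ds["sic"].attrs.update(long_name="sea_ice_area_fraction", units="1")
        ds["land_mask"].attrs.update(long_name="land_binary_mask", units="1")
        ds.to_netcdf(str(path), engine="scipy")

    @staticmethod
    def from_netcdf(path) -> "IceField":
        ds = xr.load_dataset(str(path), engine="scipy")
        proj = LaeaProjection(
            lon_0=float(ds.attrs.get("proj_lon_0", 0.0)),
            lat_0=float(ds.attrs.get("proj_lat_0", 90.0)),
        )
        return IceField(ds, proj)


@dataclass
class HerdLocations:
    """Herd coordinates (WGS84 degrees) mapped to analysis populations."""

    table: pd.DataFrame  # columns: herd, population, lon, lat

    def __post_init__(self) -> None:
        required = {"herd", "population", "lon", "lat"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"herd table missing columns: {sorted(missing)}")
        if (self.table["lat"].abs() > 90).any():
            raise ValueError("latitudes outside [-90, 90]")

    @staticmethod
    def from_tsv(path) -> "HerdLocations":
        return HerdLocations(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))


# --------------------------------------------------------------------------
# centroids and buffer sampling
# --------------------------------------------------------------------------


def population_centroid(herds: HerdLocations, population: str, proj: LaeaProjection):
    """Mean of the population's herd coordinates on the projected plane (km)."""
    sub = herds.table[herds.table["population"] == population]
    if sub.empty:
        raise ValueError(f"population {population!r} has no herds")
    x, y = proj.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    return float(np.mean(x)), float(np.mean(y))


def centroid_and_buffer(
    herds: HerdLocations,
    populations: tuple[str, str] | list[str],
    proj: LaeaProjection,
    buffer_km: float = 100.0,
    n_points: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Event centroid (midpoint of population centroids) plus uniform random
    points within ``buffer_km`` of it; returns an (n_points, 2) array in km.

    Points are uniform over the disc area: radius r = R sqrt(u), angle
    uniform.
    """
    cents = np.array([population_centroid(herds, p, proj) for p in populations])
    center = cents.mean(axis=0)
    rng = np.random.default_rng(seed)
    u = rng.random(n_points)
    theta = rng.uniform(0, 2 * np.pi, n_points)
    r = buffer_km * np.sqrt(u)
    pts = np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])
    return pts


# --------------------------------------------------------------------------
# extraction
# --------------------------------------------------------------------------


@dataclass
class IceSeries:
    """Mean/sd of sea-ice concentration per time slice and month, averaged
    over the sampled centroid-perturbation points.  ``month`` index includes
    the 12 calendar months plus 'annual'."""

    mean: pd.DataFrame  # index time_ka, columns months + 'annual'
    sd: pd.DataFrame
    n_cells: pd.DataFrame
    radius_km: float
    flags: dict = field(default_factory=dict)


def extract_ice_series(field: IceField, points: np.ndarray, radius_km: float) -> IceSeries:
    """Extract concentration statistics around each point and average.

    For every point, all non-land cells whose centers lie within
    ``radius_km`` contribute; mean and sd are taken over those cells, then
    averaged over points.  Slices where no point sees any ocean cell are
    flagged missing (NaN).
    """
    ds = field.ds
    xs = ds["x"].values
    ys = ds["y"].values
    cell = float(abs(xs[1] - xs[0])) if xs.size > 1 else 0.0
    if radius_km <= cell:
        raise ValueError(f"radius {radius_km} km must exceed cell size {cell} km")
    gx, gy = np.meshgrid(xs, ys)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    within = (
        (gx[None, :, :] - pts[:, 0, None, None]) ** 2
        + (gy[None, :, :] - pts[:, 1, None, None]) ** 2
    ) <= radius_km**2  # (n_points, ny, nx)

    times = field.times_ka
    cols = MONTHS + ["annual"]
    mean = pd.DataFrame(index=times, columns=cols, dtype=float)
    sd = pd.DataFrame(index=times, columns=cols, dtype=float)
    ncell = pd.DataFrame(index=times, columns=cols, dtype=float)
    flags = {}

    sic_all = ds["sic"].values  # (t, 12, ny, nx)
    land_all = ds["land_mask"].values  # (t, ny, nx)
    for ti, t in enumerate(times):
        ocean = land_all[ti] == 0
        sel = within & ocean[None, :, :]  # (n_points, ny, nx)
        counts = sel.sum(axis=(1, 2))
        if np.all(counts == 0):
            mean.loc[t] = np.nan
            sd.loc[t] = np.nan
            ncell.loc[t] = 0.0
            flags.setdefault("no_ocean_cells", []).append(float(t))
            continue
        valid = counts > 0
        monthly = sic_all[ti]  # (12, ny, nx)
        annual = monthly.mean(axis=0)
        for mi, mname in enumerate(cols):
            grid = annual if mname == "annual" else monthly[mi]
            pm = np.array([grid[s].mean() for s in sel[valid]])
            psd = np.array([grid[s].std() for s in sel[valid]])
            mean.loc[t, mname] = pm.mean()
            sd.loc[t, mname] = psd.mean()
            ncell.loc[t, mname] = counts[valid].mean()
    return IceSeries(mean=mean, sd=sd, n_cells=ncell, radius_km=radius_km, flags=flags)


def crossing_window(series: IceSeries, threshold: float = 0.70) -> pd.DataFrame:
    """Calendar months at or above the crossing threshold, per time slice.

    Returns a boolean frame (True = open for crossing, i.e. concentration
    >= threshold); missing months propagate as pandas NA.
    """
    monthly = series.mean[MONTHS]
    open_ = monthly >= threshold
    return open_.where(monthly.notna(), other=pd.NA)


# --------------------------------------------------------------------------
# event overlay
# --------------------------------------------------------------------------


@dataclass
class EventTimeline:
    """Inferred demographic events with median and 95% CI in ka."""

    table: pd.DataFrame  # columns: event, kind, median_ka, ci_low_ka, ci_high_ka

    def __post_init__(self) -> None:
        bad = self.table[
            (self.table["ci_low_ka"] > self.table["median_ka"])
            | (self.table["median_ka"] > self.table["ci_high_ka"])
        ]
        if len(bad):
            raise ValueError(f"CI must bracket the median: {bad['event'].tolist()}")


def nearest_slice(t_ka: float, slices: np.ndarray) -> float:
    """Nearest 1 ka slice; exact half-ka ties resolve toward the older slice.

    Events older than the oldest slice are clamped to it.
    """
    slices = np.sort(np.asarray(slices, dtype=float))
    step = slices[1] - slices[0] if slices.size > 1 else 1.0
    snapped = np.floor(t_ka / step + 0.5) * step
    return float(np.clip(snapped, slices[0], slices[-1]))


def overlay_events(
    timeline: EventTimeline, series: IceSeries, threshold: float = 0.70
) -> pd.DataFrame:
    """Map each event's median and CI bounds to the nearest slice and tabulate
    the annual ice mean±sd and open crossing months there."""
    slices = series.mean.index.to_numpy(dtype=float)
    rows = []
    open_months = crossing_window(series, threshold)
    for _, ev in timeline.table.iterrows():
        s_med = nearest_slice(ev["median_ka"], slices)
        s_lo = nearest_slice(ev["ci_low_ka"], slices)
        s_hi = nearest_slice(ev["ci_high_ka"], slices)
        months = open_months.loc[s_med]
        rows.append(
            {
                "event": ev["event"],
                "kind": ev["kind"],
                "median_ka": ev["median_ka"],
                "slice_ka": s_med,
                "ci_slice_low_ka": s_lo,
                "ci_slice_high_ka": s_hi,
                "annual_mean": series.mean.loc[s_med, "annual"],
                "annual_sd": series.sd.loc[s_med, "annual"],
                "open_months": ",".join(
                    m for m in MONTHS
                    if months[m] is not pd.NA and not pd.isna(months[m]) and bool(months[m])
                ),
            }
        )
    return pd.DataFrame(rows)


def plot_overlay(timeline: EventTimeline, series: IceSeries, ax=None, months=None):
    """Time-series plot of ice cover with dashed event medians and dotted CIs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    t = series.mean.index.to_numpy(dtype=float)
    ax.fill_between(
        t,
        series.mean["annual"] - series.sd["annual"],
        series.mean["annual"] + series.sd["annual"],
        alpha=0.25,
        label="annual mean ± sd",
    )
    ax.plot(t, series.mean["annual"], lw=1.5)
    for m in months or []:
        ax.plot(t, series.mean[m], lw=0.8, alpha=0.7, label=m)
    for _, ev in timeline.table.iterrows():
        ax.axvline(ev["median_ka"], ls="--", color="k", lw=1)
        ax.axvline(ev["ci_low_ka"], ls=":", color="k", lw=0.8)
        ax.axvline(ev["ci_high_ka"], ls=":", color="k", lw=0.8)
    ax.set_xlabel("ka before present")
    ax.set_ylabel("sea-ice concentration")
    ax.set_xlim(t.max(), t.min())
    ax.set_ylim(0, 1)
    ax.legend(loc="best", fontsize=8)
    return ax
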