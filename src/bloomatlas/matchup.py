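"""Satellite vs in situ phenology validation at monitoring stations.

A satellite ocean-colour sensor sees roughly the first optical depth of
the water column, Z90 = 1/Kd(490).  To compare a surface satellite
retrieval with a discrete-depth bottle profile, the profile is linearly
interpolated to a 1-m grid (1–75 m) and depth-averaged over [1, Z90] with
the trapezoidal rule, giving a concentration directly comparable to the
satellite value.  Matchups are same-day, same-station pairs; both streams
are then resampled to 7-day composites, climatologies are built, and the
growth-period detector is run on each so the timing metrics can be
differenced (satellite minus in situ) in whole composites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .calendar import N_BINS
from .climatology import climatology_from_weekly
from .phenology import DetectorConfig, PhenologyMetrics, detect_growth_period

__all__ = [
    "first_optical_depth",
    "integrate_profile_to_z90",
    "extract_satellite_at_station",
    "build_matchups",
    "PhenologyComparison",
    "compare_phenology",
    "read_station_csv",
]

_DEPTH_GRID_MAX = 75.0  # m; interpolation grid spans 1..75 m at 1-m steps


def first_optical_depth(kd490: float) -> float:
    """First optical depth Z90 = 1/Kd(490), in metres."""
    kd = float(kd490)
    if not np.isfinite(kd) or kd <= 0:
        raise ValueError("Kd(490) must be a positive finite number")
    return 1.0 / kd


def integrate_profile_to_z90(depths, chl, z90: float) -> float:
    """Depth-averaged Chl-a over the first optical depth (mg m-3).

    The profile is linearly interpolated onto a 1-m grid from 1 to 75 m
    (values beyond the sampled depth range take the nearest sample) and
    averaged over [1, min(z90, 75)] m with the trapezoidal rule, i.e. the
    trapezoidal integral divided by the layer thickness.  A single-depth
    profile falls back to that value with a warning; a Z90 at or above the
    1-m grid start but below the shallowest sample simply returns the
    shallowest value via nearest extension.
    """
    if z90 <= 0:
        raise ValueError("z90 must be positive")
    d = np.asarray(depths, dtype=float)
    c = np.asarray(chl, dtype=float)
    if d.shape != c.shape or d.ndim != 1 or len(d) == 0:
        raise ValueError("depths and chl must be matching non-empty 1-D arrays")
    order = np.argsort(d)
    d, c = d[order], c[order]
    if len(d) == 1:
        warnings.warn("single-depth profile: returning the sample value "
                      "instead of a depth average", stacklevel=2)
        return float(c[0])
    z_top = 1.0
    z_bot = min(float(z90), _DEPTH_GRID_MAX)
    if z_bot <= z_top:
        # optical depth within the first metre: surface-most value
        return float(np.interp(z_bot, d, c))
    grid = np.arange(z_top, np.floor(z_bot) + 1.0)
    if grid[-1] < z_bot:
        grid = np.append(grid, z_bot)
    prof = np.interp(grid, d, c)  # np.interp extends by edge values
    return float(np.trapezoid(prof, grid) / (z_bot - z_top))


def extract_satellite_at_station(field: xr.DataArray, lon: float, lat: float,
                                 dates, window: int = 0) -> pd.Series:
    """Nearest-pixel daily satellite Chl-a at a station for given dates.

    ``window > 0`` averages a (2*window+1)-pixel box around the nearest
    pixel instead (non-default; the default honours exact station
    locations).  Masked days come back as NaN, never zero.  Stations
    outside the grid bounds raise ``ValueError``.
    """
    lons = field["lon"].values
    lats = field["lat"].values

    def _inside(x, grid):
        lo, hi = grid.min(), grid.max()
        step = np.median(np.abs(np.diff(grid))) if len(grid) > 1 else 0.0
        return lo - step / 2 <= x <= hi + step / 2

    if not (_inside(lon, lons) and _inside(lat, lats)):
        raise ValueError(f"station ({lon}, {lat}) lies outside the grid")
    j = int(np.argmin(np.abs(lons - lon)))
    i = int(np.argmin(np.abs(lats - lat)))
    if window > 0:
        sl_lat = slice(max(i - window, 0), i + window + 1)
        sl_lon = slice(max(j - window, 0), j + window + 1)
        pix = field.isel(lat=sl_lat, lon=sl_lon).mean(dim=("lat", "lon"),
                                                      skipna=True)
    else:
        pix = field.isel(lat=i, lon=j)
    series = pd.Series(pix.values, index=pd.DatetimeIndex(field["time"].values))
    want = pd.DatetimeIndex(dates)
    return series.reindex(want)


def build_matchups(station_records: pd.DataFrame, kd_series: pd.Series,
                   field: xr.DataArray, lon: float, lat: float,
                   window: int = 0) -> pd.DataFrame:
    """Same-day satellite / depth-integrated in situ Chl-a matchup table.

    ``station_records`` holds dated depth profiles (columns date, depth_m,
    chl_mg_m3); ``kd_series`` daily Kd(490) indexed by date.  For each
    profile date with a Kd value, the profile is integrated over Z90 and
    paired with the same-day nearest-pixel satellite value.  Columns:
    date, satellite_chl, insitu_chl_z90, z90_m.
    """
    records = station_records.copy()
    records["date"] = pd.to_datetime(records["date"])
    kd = pd.Series(kd_series.values, index=pd.DatetimeIndex(kd_series.index))
    rows = []
    for date, prof in records.groupby("date"):
        if date not in kd.index or pd.isna(kd.loc[date]):
            continue
        z90 = first_optical_depth(kd.loc[date])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            integ = integrate_profile_to_z90(prof["depth_m"].to_numpy(),
                                             prof["chl_mg_m3"].to_numpy(), z90)
        rows.append({"date": date, "insitu_chl_z90": integ, "z90_m": z90})
    pairs = pd.DataFrame(rows)
    if pairs.empty:
        return pd.DataFrame(columns=["date", "satellite_chl",
                                     "insitu_chl_z90", "z90_m"])
    sat = extract_satellite_at_station(field, lon, lat, pairs["date"], window)
    pairs["satellite_chl"] = sat.to_numpy()
    return pairs[["date", "satellite_chl", "insitu_chl_z90", "z90_m"]]


@dataclass
class PhenologyComparison:
    """Satellite-minus-in situ phenology offsets, in composites/days."""

    satellite: PhenologyMetrics
    insitu: PhenologyMetrics
    initiation_offset: Optional[int] = None
    peak_offset: Optional[int] = None
    termination_offset: Optional[int] = None
    duration_diff_days: Optional[int] = None

    @property
    def valid(self) -> bool:
        return self.satellite.bloom_found and self.insitu.bloom_found


def _signed_circular_offset(a: int, b: int) -> int:
    """Signed shortest circular difference a - b on the 52-composite ring."""
    d = (int(a) - int(b)) % N_BINS
    return d - N_BINS if d > N_BINS // 2 else d


def compare_phenology(insitu_weekly: pd.Series, satellite_weekly: pd.Series,
                      config: DetectorConfig = DetectorConfig()
                      ) -> PhenologyComparison:
    """Difference the growth-period metrics of two weekly Chl-a series.

    Both series are (cycle_year, bin)-indexed 7-day composites (see
    :func:`bloomatlas.climatology.weekly_binned_series`); each is pooled
    into a climatology and run through the detector.  Offsets are
    satellite minus in situ in signed composites (negative = satellite
    earlier); the result is flagged invalid when either stream has no
    detectable bloom.
    """
    clim_in = climatology_from_weekly(insitu_weekly, origin="insitu")
    clim_sat = climatology_from_weekly(satellite_weekly, origin="satellite")
    m_in = detect_growth_period(clim_in, config)
    m_sat = detect_growth_period(clim_sat, config)
    cmp_ = PhenologyComparison(m_sat, m_in)
    if cmp_.valid:
        cmp_.initiation_offset = _signed_circular_offset(
            m_sat.initiation_bin, m_in.initiation_bin)
        cmp_.peak_offset = _signed_circular_offset(m_sat.peak_bin, m_in.peak_bin)
        cmp_.termination_offset = _signed_circular_offset(
            m_sat.termination_bin, m_in.termination_bin)
        cmp_.duration_diff_days = m_sat.duration_days - m_in.duration_days
    return cmp_


def read_station_csv(path) -> pd.DataFrame:
    """Read station profile records (date, lon, lat, depth_m, chl_mg_m3)."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "lon", "lat", "depth_m", "chl_mg_m3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"station CSV missing columns: {sorted(missing)}")
    return df
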