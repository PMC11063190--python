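"""Weekly (7-day composite) climatologies on the August–July calendar.

A climatology is the multi-year mean seasonal cycle: every unmasked daily
observation is assigned to one of 52 composites (see
:mod:`bloomatlas.calendar`) and averaged across all years jointly.  Pooling
across years is what makes the cycle gap-free even when individual days are
lost to cloud cover — provided every composite receives at least one
observation over the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .calendar import N_BINS, composite_index_series

__all__ = [
    "WeeklyClimatology",
    "build_weekly_climatology",
    "build_weekly_climatology_field",
    "weekly_binned_series",
    "climatology_from_weekly",
]


@dataclass
class WeeklyClimatology:
    """52-composite mean seasonal cycle for one pixel or region.

    Parameters
    ----------
    values : ndarray, shape (52,)
        Mean Chl-a (mg m-3) per composite; NaN where a composite received
        no observations.
    support : ndarray, shape (52,)
        Number of daily observations contributing to each composite.
    origin : str
        Free-text provenance (pixel index, region name, station id).
    """

    values: np.ndarray
    support: np.ndarray = field(default=None)  # type: ignore[assignment]
    origin: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"climatology must have {N_BINS} composites, "
                             f"got shape {self.values.shape}")
        if self.support is None:
            self.support = np.where(np.isnan(self.values), 0, 1)
        self.support = np.asarray(self.support, dtype=int)
        if self.support.shape != (N_BINS,):
            raise ValueError("support must have 52 entries")

    @property
    def bins(self) -> np.ndarray:
        return np.arange(1, N_BINS + 1)

    @property
    def complete(self) -> bool:
        """True when every composite has support and a finite value."""
        return bool(np.all(self.support >= 1) and np.all(np.isfinite(self.values)))

    def median(self) -> float:
        return float(np.median(self.values))

    def mean(self) -> float:
        """Climatology mean ("MeanChl-a"): mean over all 52 composites."""
        return float(np.mean(self.values))

    def max(self) -> float:
        return float(np.max(self.values))

    def scaled(self, factor: float) -> "WeeklyClimatology":
        return WeeklyClimatology(self.values * factor, self.support, self.origin)


def _as_daily_series(obj) -> pd.Series:
    if isinstance(obj, pd.Series):
        return obj
    if isinstance(obj, xr.DataArray):
        if obj.ndim != 1:
            raise ValueError("expected a 1-D (time) DataArray")
        return obj.to_series()
    raise TypeError(f"cannot interpret {type(obj)!r} as a daily series")


def build_weekly_climatology(series, origin: str = "") -> WeeklyClimatology:
    """Build the 52-composite climatology of a dated scalar Chl-a series.

    Each composite's value is the arithmetic mean of every non-missing
    observation mapped to it across all years; the number of contributing
    observations is recorded as support.
    """
    s = _as_daily_series(series).dropna()
    values = np.full(N_BINS, np.nan)
    support = np.zeros(N_BINS, dtype=int)
    if len(s):
        bins = composite_index_series(s.index)
        grouped = pd.Series(s.to_numpy(), index=bins).groupby(level=0)
        m, c = grouped.mean(), grouped.count()
        values[m.index.to_numpy() - 1] = m.to_numpy()
        support[c.index.to_numpy() - 1] = c.to_numpy()
    return WeeklyClimatology(values, support, origin)


def build_weekly_climatology_field(field: xr.DataArray) -> xr.Dataset:
    """Per-pixel weekly climatology of a (time, lat, lon) Chl-a field.

    Returns a Dataset with variables ``chl`` (mean per composite, NaN where
    unsupported) and ``support`` (observation count), dims (bin, lat, lon).
    Masked values are encoded as NaN in the input.
    """
    bins = composite_index_series(field["time"].values)
    f = field.assign_coords(bin=("time", bins))
    grouped = f.groupby("bin")
    mean = grouped.mean(skipna=True)
    support = grouped.count()
    full = xr.DataArray(np.arange(1, N_BINS + 1), dims="bin", name="bin")
    mean = mean.reindex(bin=full)
    support = support.reindex(bin=full, fill_value=0)
    return xr.Dataset({"chl": mean, "support": support.astype(int)})


def pixel_climatology(clim_field: xr.Dataset, ilat: int, ilon: int) -> WeeklyClimatology:
    """Extract one pixel's :class:`WeeklyClimatology` from a per-pixel Dataset."""
    return WeeklyClimatology(
        clim_field["chl"].isel(lat=ilat, lon=ilon).values,
        clim_field["support"].isel(lat=ilat, lon=ilon).values,
        origin=f"pixel[{ilat},{ilon}]",
    )


def weekly_binned_series(daily: pd.Series) -> pd.Series:
    """Resample a dated daily series into 7-day composite means.

    Composites are anchored on the August–July phenological calendar, so the
    result is indexed by (cycle_year, bin) where ``cycle_year`` is the year
    the phenological year begins.  Composites with no observations are
    missing (NaN), not zero — downstream climatology pooling handles gaps.
    """
    s = _as_daily_series(daily)
    idx = pd.DatetimeIndex(s.index)
    cycle_year = np.where(idx.month >= 8, idx.year, idx.year - 1)
    bins = composite_index_series(idx)
    out = (
        pd.Series(s.to_numpy(), index=pd.MultiIndex.from_arrays(
            [cycle_year, bins], names=["cycle_year", "bin"]))
        .groupby(level=["cycle_year", "bin"])
        .mean()
    )
    # materialise empty composites inside the observed span as NaN
    years = range(cycle_year.min(), cycle_year.max() + 1)
    full = pd.MultiIndex.from_product([list(years), range(1, N_BINS + 1)],
                                      names=["cycle_year", "bin"])
    out = out.reindex(full)
    first = out.first_valid_index()
    last = out.last_valid_index()
    return out.loc[first:last]


def climatology_from_weekly(weekly: pd.Series, origin: str = "") -> WeeklyClimatology:
    """Average a (cycle_year, bin)-indexed weekly series across years."""
    grouped = weekly.dropna().groupby(level="bin")
    values = np.full(N_BINS, np.nan)
    support = np.zeros(N_BINS, dtype=int)
    m, c = grouped.mean(), grouped.count()
    if len(m):
        values[m.index.to_numpy() - 1] = m.to_numpy()
        support[c.index.to_numpy() - 1] = c.to_numpy()
    return WeeklyClimatology(values, support, origin)
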