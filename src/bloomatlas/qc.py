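"""Sliding-window median screening of daily Chl-a fields.

Gridded ocean-colour archives occasionally contain corrupted daily files
(e.g. interpolation errors).  Before any temporal averaging, the grid is
tiled into non-overlapping windows (default 10 x 10 pixels); each window's
spatial-mean time series is compared against its own temporal median, and
a date on which the window mean departs from the median by more than
``k`` times the median (default k = 2, strict inequality) is anomalous
for that window.  A date is flagged — and excluded downstream — when the
fraction of windows anomalous on it exceeds ``date_flag_fraction``.

Because the rule is relative to the median it is invariant to rescaling
the field by any positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["QCReport", "flag_anomalous_dates", "drop_flagged_dates"]


@dataclass
class QCReport:
    """Outcome of sliding-window median screening."""

    flagged_dates: pd.DatetimeIndex
    per_date_anomalous_fraction: pd.Series
    window_size: int
    k: float
    date_flag_fraction: float
    n_windows: int
    skipped_windows: int  # windows with no unmasked data at all

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table: date, anomalous_fraction, flagged."""
        return pd.DataFrame({
            "date": self.per_date_anomalous_fraction.index,
            "anomalous_fraction": self.per_date_anomalous_fraction.to_numpy(),
            "flagged": self.per_date_anomalous_fraction.index.isin(
                self.flagged_dates),
        })


def _tile_slices(n: int, size: int) -> list[slice]:
    """Non-overlapping tiles anchored at the origin; a trailing partial
    tile is kept when it spans at least half a window."""
    edges = list(range(0, n, size))
    slices = []
    for e in edges:
        stop = min(e + size, n)
        if stop - e >= size or stop - e >= (size + 1) // 2:
            slices.append(slice(e, stop))
    return slices


def flag_anomalous_dates(
    field: xr.DataArray,
    window_size: int = 10,
    k: float = 2.0,
    date_flag_fraction: float = 0.005,
) -> QCReport:
    """Screen a (time, lat, lon) Chl-a field for anomalous dates.

    Raises ``ValueError`` for fields shorter than two time steps (a
    temporal median of one observation flags nothing meaningfully).
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if k <= 0:
        raise ValueError("k must be > 0")
    if field.sizes["time"] < 2:
        raise ValueError("field must have at least 2 time steps")

    values = field.transpose("time", "lat", "lon").values
    nt, nlat, nlon = values.shape
    lat_slices = _tile_slices(nlat, window_size)
    lon_slices = _tile_slices(nlon, window_size)

    window_means = []
    skipped = 0
    for sl_lat in lat_slices:
        for sl_lon in lon_slices:
            tile = values[:, sl_lat, sl_lon].reshape(nt, -1)
            if np.all(np.isnan(tile)):
                skipped += 1
                continue
            with np.errstate(invalid="ignore"):
                window_means.append(np.nanmean(tile, axis=1))
    n_windows = len(window_means)
    dates = pd.DatetimeIndex(field["time"].values)
    if n_windows == 0:
        frac = pd.Series(np.zeros(nt), index=dates)
        return QCReport(dates[:0], frac, window_size, k,
                        date_flag_fraction, 0, skipped)

    series = np.stack(window_means)                    # (W, T)
    medians = np.nanmedian(series, axis=1)             # (W,)
    # strict inequality; the small relative tolerance keeps exact-boundary
    # cases (|v - m| == k*m) unflagged in floating point
    with np.errstate(invalid="ignore"):
        anomalous = (np.abs(series - medians[:, None])
                     > k * medians[:, None] * (1.0 + 1e-9))
    valid = ~np.isnan(series)
    n_valid = valid.sum(axis=0)                        # windows with data per date
    n_anom = (anomalous & valid).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_valid > 0, n_anom / np.maximum(n_valid, 1), 0.0)
    frac_s = pd.Series(frac, index=dates)
    flagged = dates[frac > date_flag_fraction]
    return QCReport(flagged, frac_s, window_size, k, date_flag_fraction,
                    n_windows, skipped)


def drop_flagged_dates(field: xr.DataArray, report: QCReport) -> xr.DataArray:
    """Remove flagged dates from a field prior to climatology building."""
    keep = ~pd.DatetimeIndex(field["time"].values).isin(report.flagged_dates)
    return field.isel(time=np.flatnonzero(keep))
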