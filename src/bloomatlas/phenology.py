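"""Threshold / cumulative-sums-of-anomalies bloom phenology detector.

The detector characterises the *main* phytoplankton growth period of a
52-composite weekly Chl-a climatology:

1. a bloom threshold is set at the long-term median of the cycle plus a
   fixed percentage (default 10%, applied multiplicatively so the timing
   metrics are invariant to rescaling the chlorophyll values);
2. anomalies (climatology minus threshold) are accumulated into cumulative
   sums;
3. the gradient of the cumulative sums — which recovers the anomalies —
   is smoothed with a circular Gaussian filter;
4. maximal runs of positive smoothed gradient are traced circularly over
   the 52 composites, and the run containing the climatology maximum is
   reported as the main growth period.  Initiation is the first composite
   of that run, termination the last, the peak is the composite of maximum
   climatological Chl-a within it, and duration is 7 days per composite
   from initiation to termination inclusive.

Secondary blooms are deliberately ignored: only the run around the
climatology maximum is characterised.

The module exposes both a functional surface (:func:`bloom_threshold`,
:func:`detect_growth_period`, ...) and a model/results pair
(:class:`ThresholdPhenology` / :class:`PhenologyResults`) for interactive
work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .calendar import N_BINS, bins_between, render_week_label
from .climatology import (
    WeeklyClimatology,
    build_weekly_climatology,
    climatology_from_weekly,
)

__all__ = [
    "DetectorConfig",
    "PhenologyMetrics",
    "bloom_threshold",
    "cumulative_anomalies",
    "smoothed_gradient",
    "positive_runs",
    "detect_growth_period",
    "duration_days",
    "ThresholdPhenology",
    "PhenologyResults",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the threshold-criterion detector.

    threshold_percent
        Percentage above the 52-composite median at which growth is "on".
        10% is a middle-of-the-road choice: lower values stretch the
        detected period and admit secondary blooms, higher values can
        overshoot the seasonal maximum entirely in weakly seasonal waters.
    smoothing_sigma
        Standard deviation (in composites) of the circular Gaussian applied
        to the gradient of the cumulative anomaly sums; 0 disables
        smoothing, in which case the sign of the gradient is exactly the
        above/below-threshold condition.
    threshold_mode
        ``"multiplicative"`` (default): threshold = median x (1 + p/100),
        scale-invariant.  ``"additive"``: threshold = median + p/100 mg m-3,
        exposed for sensitivity studies.
    """

    threshold_percent: float = 10.0
    smoothing_sigma: float = 1.0
    threshold_mode: str = "multiplicative"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_percent <= 100.0:
            raise ValueError("threshold_percent must be in [0, 100]")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.threshold_mode not in ("multiplicative", "additive"):
            raise ValueError("threshold_mode must be 'multiplicative' or 'additive'")


@dataclass
class PhenologyMetrics:
    """Timing and magnitude metrics of the main growth period."""

    bloom_found: bool
    initiation_bin: Optional[int] = None
    peak_bin: Optional[int] = None
    termination_bin: Optional[int] = None
    duration_days: Optional[int] = None
    max_chl: Optional[float] = None
    growth_mean_chl: Optional[float] = None
    climatology_mean_chl: Optional[float] = None
    origin: str = ""

    def as_dict(self) -> dict:
        return {
            "bloom_found": self.bloom_found,
            "initiation_bin": self.initiation_bin,
            "peak_bin": self.peak_bin,
            "termination_bin": self.termination_bin,
            "duration_days": self.duration_days,
            "max_chl": self.max_chl,
            "growth_mean_chl": self.growth_mean_chl,
            "climatology_mean_chl": self.climatology_mean_chl,
        }


def bloom_threshold(clim: WeeklyClimatology, config: DetectorConfig = DetectorConfig()) -> float:
    """Bloom threshold: the long-term median plus ``threshold_percent``."""
    if not clim.complete:
        raise ValueError("climatology is incomplete (some composites lack support); "
                         "cannot compute a bloom threshold")
    med = clim.median()
    if config.threshold_mode == "multiplicative":
        return med * (1.0 + config.threshold_percent / 100.0)
    return med + config.threshold_percent / 100.0


def cumulative_anomalies(clim: WeeklyClimatology, threshold: float) -> np.ndarray:
    """Running sum of (climatology - threshold) over the 52 composites."""
    return np.cumsum(clim.values - threshold)


def smoothed_gradient(cumsum_series: np.ndarray, sigma: float) -> np.ndarray:
    """Gradient of the cumulative sums, Gaussian-smoothed on the circle.

    The first difference of the cumulative sums recovers the anomaly
    series (the first element is the first anomaly itself); the seasonal
    cycle is periodic, so smoothing wraps around the August boundary.
    ``sigma = 0`` returns the raw gradient.
    """
    cs = np.asarray(cumsum_series, dtype=float)
    grad = np.diff(cs, prepend=0.0)
    if sigma > 0:
        grad = gaussian_filter1d(grad, sigma=sigma, mode="wrap")
    return grad


def positive_runs(values: np.ndarray) -> list[list[int]]:
    """Maximal circular runs of strictly positive entries, as 0-based index lists.

    Runs are traced circularly so a growth period straddling the Jul/Aug
    boundary is reported as a single run.  Returned runs start at their
    first composite in circular order; ordering of runs follows their start.
    """
    pos = np.asarray(values) > 0
    n = len(pos)
    if pos.all():
        return [list(range(n))]
    if not pos.any():
        return []
    runs: list[list[int]] = []
    # rotate so position 0 is non-positive: runs never wrap after rotation
    start = int(np.argmin(pos))  # first False
    current: list[int] = []
    for offset in range(n):
        i = (start + offset) % n
        if pos[i]:
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    runs.sort(key=lambda r: r[0])
    return runs


def detect_growth_period(
    clim: WeeklyClimatology, config: DetectorConfig = DetectorConfig()
) -> PhenologyMetrics:
    """Detect the main growth period of a complete weekly climatology.

    The main period is the positive run of the smoothed gradient that
    contains the composite of maximum climatological Chl-a (ties broken by
    the earliest composite after 1 August); if the maximum falls in no
    positive run, the run holding the largest climatology value among its
    members is taken.  Returns ``bloom_found=False`` when the gradient is
    nowhere positive.
    """
    threshold = bloom_threshold(clim, config)
    cs = cumulative_anomalies(clim, threshold)
    grad = smoothed_gradient(cs, config.smoothing_sigma)
    runs = positive_runs(grad)
    clim_mean = clim.mean()
    if not runs:
        return PhenologyMetrics(False, climatology_mean_chl=clim_mean,
                                origin=clim.origin)
    peak0 = int(np.argmax(clim.values))  # argmax: earliest bin on ties
    main = None
    for run in runs:
        if peak0 in run:
            main = run
            break
    if main is None:
        main = max(runs, key=lambda r: np.max(clim.values[r]))
    init_bin = main[0] + 1
    term_bin = main[-1] + 1
    run_vals = clim.values[main]
    peak_bin = main[int(np.argmax(run_vals))] + 1
    return PhenologyMetrics(
        bloom_found=True,
        initiation_bin=init_bin,
        peak_bin=peak_bin,
        termination_bin=term_bin,
        duration_days=duration_days(init_bin, term_bin),
        max_chl=float(clim.values[peak_bin - 1]),
        growth_mean_chl=float(np.mean(run_vals)),
        climatology_mean_chl=clim_mean,
        origin=clim.origin,
    )


def duration_days(initiation_bin: int, termination_bin: int) -> int:
    """Growth-period duration: 7 days per composite, initiation to
    termination inclusive, counted circularly."""
    return 7 * bins_between(initiation_bin, termination_bin)


class ThresholdPhenology:
    """Bloom-phenology model for one weekly Chl-a climatology.

    Parameters
    ----------
    climatology : WeeklyClimatology
        A complete 52-composite seasonal cycle.
    threshold_percent, smoothing_sigma, threshold_mode
        See :class:`DetectorConfig`.

    Examples
    --------
    >>> from bloomatlas.synthetic import BloomTruth, generate_mean_cycle
    >>> clim = generate_mean_cycle(BloomTruth(seed=0))
    >>> res = ThresholdPhenology(clim).fit()
    >>> res.metrics.bloom_found
    True
    """

    def __init__(self, climatology: WeeklyClimatology,
                 threshold_percent: float = 10.0,
                 smoothing_sigma: float = 1.0,
                 threshold_mode: str = "multiplicative"):
        if not isinstance(climatology, WeeklyClimatology):
            raise TypeError("climatology must be a WeeklyClimatology")
        if not climatology.complete:
            raise ValueError("climatology is incomplete; every composite needs "
                             "at least one supporting observation")
        self.climatology = climatology
        self.config = DetectorConfig(threshold_percent, smoothing_sigma,
                                     threshold_mode)

    @classmethod
    def from_daily_series(cls, series: pd.Series, origin: str = "", **kwargs
                          ) -> "ThresholdPhenology":
        """Build the model from a dated daily Chl-a series (pools all years)."""
        return cls(build_weekly_climatology(series, origin=origin), **kwargs)

    @classmethod
    def from_weekly_series(cls, weekly: pd.Series, origin: str = "", **kwargs
                           ) -> "ThresholdPhenology":
        """Build the model from a (cycle_year, bin)-indexed weekly series."""
        return cls(climatology_from_weekly(weekly, origin=origin), **kwargs)

    def fit(self) -> "PhenologyResults":
        threshold = bloom_threshold(self.climatology, self.config)
        cs = cumulative_anomalies(self.climatology, threshold)
        grad = smoothed_gradient(cs, self.config.smoothing_sigma)
        metrics = detect_growth_period(self.climatology, self.config)
        return PhenologyResults(self, threshold, cs, grad, metrics)


@dataclass
class PhenologyResults:
    """Fitted phenology: metrics plus the detector's intermediate series."""

    model: ThresholdPhenology
    threshold: float
    cumulative_sums: np.ndarray
    gradient: np.ndarray = field(repr=False)
    metrics: PhenologyMetrics = field(default=None)  # type: ignore[assignment]

    @property
    def bloom_found(self) -> bool:
        return self.metrics.bloom_found

    def summary(self) -> str:
        """Plain-text summary table of the detected growth period."""
        clim = self.model.climatology
        cfg = self.model.config
        lines = [
            "Threshold-criterion bloom phenology",
            "=" * 43,
            f"origin:             {clim.origin or '-'}",
            f"threshold:          {self.threshold:.4f} mg m-3 "
            f"(median + {cfg.threshold_percent:g}%, {cfg.threshold_mode})",
            f"smoothing sigma:    {cfg.smoothing_sigma:g} composites",
            f"climatology mean:   {clim.mean():.4f} mg m-3",
        ]
        m = self.metrics
        if not m.bloom_found:
            lines.append("bloom found:        no")
        else:
            lines += [
                "bloom found:        yes",
                f"initiation:         week {m.initiation_bin:2d}  "
                f"({render_week_label(m.initiation_bin, 'onset')})",
                f"peak:               week {m.peak_bin:2d}  "
                f"({render_week_label(m.peak_bin, 'onset')})",
                f"termination:        week {m.termination_bin:2d}  "
                f"({render_week_label(m.termination_bin, 'end')})",
                f"duration:           {m.duration_days} days "
                f"({m.duration_days // 7} composites)",
                f"max Chl-a:          {m.max_chl:.4f} mg m-3",
                f"growth-period mean: {m.growth_mean_chl:.4f} mg m-3",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the climatology, threshold, and detected growth period."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        clim = self.model.climatology
        ax.plot(clim.bins, clim.values, marker="o", ms=3, lw=1.2,
                color="tab:green", label="weekly climatology")
        ax.axhline(self.threshold, color="tab:red", lw=1,
                   label=f"threshold ({self.threshold:.3g})")
        m = self.metrics
        if m.bloom_found:
            for b, name in ((m.initiation_bin, "initiation"),
                            (m.termination_bin, "termination")):
                ax.axvline(b, color="0.4", ls="--", lw=1)
            ax.axvline(m.peak_bin, color="tab:orange", ls=":", lw=1,
                       label="peak")
        ax.set_xlabel("composite (1 = week of 1 Aug)")
        ax.set_ylabel("Chl-a (mg m$^{-3}$)")
        ax.legend(fontsize=8)
        return ax
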