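# Methods

## The phenology model

The package treats a pixel's (or region's) seasonal Chl-a cycle as a
52-point weekly climatology `C(w)` on an August-anchored year and defines
the growth period through a relative threshold:

```
T        = median(C) · (1 + p/100),          p = 10 by default
A(w)     = C(w) − T
S(w)     = Σ_{j ≤ w} A(j)                    (cumulative sums of anomalies)
G(w)     = smooth_σ( ΔS )(w)                 (ΔS recovers A; circular Gaussian)
```

Maximal circular runs of `G > 0` are candidate growth periods; the run
containing the composite of maximum `C` is reported as the *main* period
(secondary blooms are deliberately not characterised). Initiation and
termination are the first and last composites of that run, the peak the
argmax of `C` inside it, and duration is `7 × (inclusive composite
count)`. With `σ = 0` the sign of `G` is exactly the above/below-threshold
condition, so the detector degenerates to "first/last composite above
threshold around the maximum" — a property the test suite checks against
an independent brute-force oracle on 1,000 random unimodal cycles.

Assumptions: the cycle is periodic (runs are traced circularly across the
Jul/Aug boundary); one growth period dominates; the climatology is
complete (every composite supported by at least one observation — pooling
across years supplies this even with heavy cloud gaps). Incomplete
climatologies are rejected rather than interpolated.

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| `threshold_percent` | 10 | % of median | middle of the 5–20% range used for seasonal bloom criteria; lower values stretch periods and admit secondary blooms, higher ones can overshoot weak seasonal maxima entirely |
| `threshold_mode` | multiplicative | — | `T = 1.1·median` makes every timing metric invariant to rescaling the field, which matters because absolute satellite Chl-a is biased in optically complex water while its *relative* seasonal course is robust; an additive mode (`median + p/100 mg m⁻³`) is exposed for sensitivity work |
| `smoothing_sigma` | 1 | composites | suppresses single-composite sign flips of the gradient without displacing crossings on smooth cycles; 0 disables smoothing |
| QC `window_size` | 10 | pixels | ~10 km tiles at 1-km resolution: large enough to average sensor noise, small enough to stay within one trophic regime |
| QC `k` | 2 | — | a window is anomalous on a date when its spatial mean departs from its temporal median m by more than `k·m` (strict inequality, with a 1e-9 relative tolerance so exact-boundary values are not flagged) |
| QC `date_flag_fraction` | 0.005 | — | a date is discarded when more than this fraction of windows is anomalous; replaces the visual confirmation step a human analyst would do, making the rule fully automatic |

### Calendar and label conventions

Day 1 of the phenological year is 1 August; composite `b` covers cycle
days `7(b−1)+1 … 7b`, and composite 52 additionally absorbs day 365 (and
366 in leap years), keeping composite 1 aligned with 1 August in every
year. Week labels in regional tables follow two conventions, both
implemented: initiation and peak weeks are printed as the composite's own
span (starting day `7k+1`), termination weeks as a span starting on the
composite's final day (`7k`). This pairing, together with
`duration = 7 × inclusive count`, reproduces the printed
initiation/termination ranges and durations of the published
Eastern-Mediterranean regional table for 17 of its 20 rows; the remaining
three rows (South Evoikos Gulf, Pelops Gyre, Ierapetra Gyre) are
internally inconsistent in the publication — their printed labels and
printed durations cannot both be right under any label convention that
preserves the other rows — and are reported as-is rather than patched.
The per-row consistency check in the test suite fails on exactly those
three rows by design.

## Synthetic data

`BloomTruth` parameterises a ground-truth cycle: baseline plus circular
Gaussian bump(s) in composite index, so blooms may straddle the year
boundary. Defaults emulate an oligotrophic temperate winter bloom:
baseline 0.1 mg m⁻³, amplitude 0.3 mg m⁻³ centred on composite 28
(mid-February) with σ = 5 composites — which puts the detected growth
period near 25 composites, inside the 23–27-week open-sea range — 20%
lognormal noise CV, 30% cloud-gap probability, 20 years. Daily values are
the day's composite mean times unit-mean multiplicative lognormal noise
(chlorophyll is positive and right-skewed; the paper-style products give
no noise model, so CV is the single free parameter); gaps are drawn
independently per pixel-day. One `numpy.random.default_rng(seed)` stream
per generator call, noise drawn before the mask, makes outputs
bit-reproducible. An optional linear west–east scale ramp emulates a
coastal-to-open trophic gradient; station profiles support constant
(well-mixed) or exponential depth shapes with matched K_d series.

What the generator does *not* emulate: spatial autocorrelation of noise
and cloud masks (real cloud gaps are highly correlated), optical-water-type
retrieval bias, interannual variability of bloom timing (every year shares
one truth cycle), and multi-day sensor outages. Passing the recovery tests
therefore shows the detector is robust to unbiased multiplicative noise
and random gaps at realistic rates, not to correlated or systematic error.

## Matchup validation

Profiles are interpolated linearly onto a 1-m grid from 1 to 75 m and
depth-averaged over `[1, min(Z₉₀, 75)]` m by the trapezoidal rule, giving
a concentration (mg m⁻³) comparable to the surface satellite retrieval;
`Z₉₀ = 1/K_d(490)` is the layer a colour sensor effectively sees. Values
outside the sampled depth range are extended with the nearest sample
(bottle casts typically start at 2 m while the grid starts at 1 m);
single-depth profiles fall back to the sample value with a warning, and a
Z₉₀ shallower than 1 m returns the interpolated value at Z₉₀. Matchups
are same-day, same-station, nearest-pixel pairs (a box-mean option
exists but is off by default). Timing offsets between the two streams'
fitted phenologies are signed shortest circular differences on the
52-composite ring, so swapping the inputs negates them.

## Numerical choices and degenerate inputs

- Peak ties and main-run ties break to the earliest composite after
  1 August.
- If Gaussian smoothing leaves the climatology-maximum composite outside
  every positive run (possible only for contrived cycles), the run with
  the largest climatology value among its members is reported.
- QC tiles are anchored at the grid origin; trailing partial tiles are
  kept when at least half a window wide, otherwise those pixels are not
  screened. All-NaN windows are skipped and counted in the report.
- The QC rule flags a date when a window mean exceeds three times its
  temporal median (or drops below −1×, impossible for positive data), so
  it presumes the seasonal amplitude of a window's series stays below
  ~3× its median — true of the Mediterranean product it mirrors, but a
  strongly pulsed synthetic bloom (amplitude ≳ 3 × baseline) will have
  genuine bloom dates flagged. Raise `k` in such experiments.
- Weekly binning of sparse series leaves empty composites as NaN;
  climatology pooling requires support in all 52 composites and refuses
  detection otherwise.

## Problem sizes

The bundled experiments use single-pixel 20-year daily fields (~7,300
observations each; 100 seeds) for parameter recovery, 1,000 random cycles
for the oracle-equivalence check, and small (≤ 12 × 12 pixel, ≤ 5-year)
grids for field-level tests — sizes at which every property under test is
already fully expressed, while the whole suite runs in seconds.

## Known limitations

- One growth period per cycle; no secondary-bloom metrics, no per-year
  (interannual) phenology, no biomass-integrated bloom magnitude.
- Rectangles only for regions; no polygon masks or bathymetry masking.
- No temporal gap-filling: the gap-free property must come from pooling.
- GeoTIFF export is not provided; atlases are written as NetCDF
  (EPSG:4326 attributes) and regional tables as CSV.
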