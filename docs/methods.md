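# Methods

## Model and procedure

The package treats climatic stress as a multidimensional property. Four
daily variables are processed independently: minimum temperature (tmin,
°C), maximum temperature (tmax, °C), and minimum/maximum vapor pressure
deficit (vpdmin/vpdmax, hPa). The underlying assumption is asymmetric:
cold nights are stressful, so tmin is *suitable at or above* a
threshold; hot days are stressful, so tmax is *suitable at or below*
one; low VPD marks excess moisture (suitable at or above), high VPD
marks atmospheric drought (suitable at or below).

Because no single threshold is biologically right for all species, the
pipeline computes suitable-day counts at every threshold across each
variable's plausible range and treats the sweep as the object of
analysis:

1. **Counting.** For each threshold, each pixel's count of suitable
   days over the climatology. Counts are monotone in the threshold by
   construction (non-increasing for suitable-above variables,
   non-decreasing for suitable-below) and bounded by the number of days.
2. **Correlation screening.** Pearson correlations among count rasters
   at different thresholds decay smoothly with threshold distance, which
   justifies a one-component summary.
3. **PCA.** The valid-pixel × threshold matrix is column-standardized
   and reduced to its first principal component. Standardization makes
   the decomposition correlation-based; without it, near-edge thresholds
   with tiny variance would be ignored entirely, and with it the choice
   of sweep endpoints matters less.
4. **Orientation.** A principal component's sign is arbitrary, so the
   score is flipped, if necessary, to correlate negatively with the mean
   suitable-day count across thresholds: high score = few suitable days
   = high stress. If that correlation is exactly zero the orientation is
   refused rather than guessed.
5. **Zonation.** The oriented PC1 is cut at its empirical 1/5…4/5
   quantiles into five classes of equal valid-pixel area, class 1 the
   least stressed.
6. **Preference.** Occurrences are cleaned, thinned, and assigned the
   zone of their containing pixel. Observed per-zone counts are tested
   against area-proportional expectations with an overall Pearson
   chi-square and per-zone 1-df zone-vs-rest chi-squares. A zone is
   *preferred* only when its per-zone test is significant and the
   observed count exceeds expectation. A species' *concentrated* zone is
   its preferred zone with the largest observed/expected ratio.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| threshold sweeps | tmin −15…15, tmax 25…50, vpdmin 0…10, vpdmax 12…30 | °C / hPa | full plausible range per variable |
| sweep step | 1 | °C / hPa | configurable; smaller steps add near-duplicate columns that standardized PCA absorbs |
| calendar | drop 29 Feb | — | 2016–2020 ⇒ exactly 5×365 = 1825 days; keeping leap days raises the cap to 1827 |
| k (classes) | 5 | — | equal-area quantile classes |
| thinning distance | 20 | km | great-circle, greedy seeded retention |
| outlier multiplier | 1.5 | IQR units | centroid-distance rule, see below |
| alpha | 0.05 | — | per-zone significance |
| correction | none | — | Holm available; "none" is the default because per-zone tests are reported individually |

## Numerical choices

- **Quantiles** use the empirical inverse-CDF (type-1) estimator, and a
  value exactly equal to a break goes to the lower class. Both choices
  are deterministic and directly checkable against a sort-and-split
  oracle; with n valid pixels and no ties at the breaks, class sizes
  differ by at most one pixel.
- **Degenerate inputs** fail loudly: an all-constant count stack, or an
  index with fewer distinct values than classes, raises a
  degenerate-input error instead of producing arbitrary zones.
  Zero-variance threshold layers are dropped from correlation matrices
  and PCA with a warning.
- **PCA** is computed by full SVD (scikit-learn), so repeated runs are
  bit-identical; the sign returned by the solver never reaches the
  user because orientation normalizes it (the zone raster is invariant
  to the solver's sign, and this is tested).
- **Counts** are stored as 16-bit integers with −1 as the nodata
  sentinel (counts live in [0, n_days]).
- **Pixel lookup** is half-open: a point on a shared edge belongs to the
  pixel to the right/below; points on the grid's top/left outer edge
  belong to the first row/column.
- **Distances** are great-circle on a sphere of radius 6371.0088 km.

## Occurrence cleaning

Cleaning applies, in order: drop records with missing coordinates, drop
(0, 0) placeholders, drop exact per-species coordinate duplicates
(keeping the first), drop records outside the area of interest, and drop
*cloud outliers*. The outlier rule is: compute each point's great-circle
distance to the species' coordinate centroid and drop points beyond
Q3 + 1.5×IQR of those distances. A single pass of that rule is not a
fixed point (removing points shrinks the quartiles), so the filter
iterates until no point is dropped (capped at 10 passes), which makes
cleaning idempotent by construction. The rule is deliberately simple and
deterministic; the multiplier is configurable and the rule can be
disabled. Every record is preserved with a status label, so input and
output record counts always agree.

Thinning retains records greedily in a seeded random order, keeping a
record iff no already-kept record of the same species lies within the
minimum distance. Different seeds give different (equally valid) maximal
sets; the guaranteed invariant — no kept pair closer than the minimum —
is what the tests assert.

## The synthetic generator

Synthetic climate is a linear spatial gradient along one axis plus a
single 365-day sinusoid (peaking at day-of-year 183, which places the
tmin trough in mid-winter) plus iid Gaussian pixel-day noise, with
per-variable defaults chosen so values span each variable's threshold
range (tmin ≈ −22…22 °C, tmax ≈ 15…50 °C, vpdmin ≈ 0…10 hPa, vpdmax ≈
10…30 hPa). An optional Gaussian smoothing radius can correlate the
noise spatially but defaults to 0: the correlation-decay structure the
zonation stage relies on emerges from the shared gradient, not from
noise autocorrelation.

What the generator does **not** emulate: topography, coastlines and
nodata footprints, spatially varying seasonal amplitude, temporally
autocorrelated weather, or station-interpolation artifacts. Passing
tests therefore demonstrate the correctness of the machinery —
thresholding, counting, reduction, classification, testing — under the
assumed structure, not the climatological fidelity of any particular
zonation of real terrain.

Synthetic occurrences are drawn per pixel with probability proportional
to the zone weight of the pixel's zone and placed uniformly within the
pixel, so with equal-area zones the expected zone shares are the
normalized weights (5:1:1:1:1 weights ⇒ 5/9 of points in the favored
zone). This is the planted signal the preference test is asked to
recover.

## Problem sizes

The default test fixture is one year of daily data on a 20×30 grid
(600 pixels, 365 days, 31 thresholds); the calendar check uses the full
5-year span on an 8×8 grid; oracle checks run on stacks up to 5×5×20;
the type-I simulation uses 1000 multinomial replicates of n = 200 and
the recovery simulation 100 seeded replicates of n = 200. These sizes
keep every property measurable with comfortable statistical margins
while the whole suite runs in seconds.

## Known limitations

- Each dimension is zoned independently; no joint multivariate
  classification is attempted, and correlations between dimensions are
  reported, not modelled.
- Expected proportions use valid-pixel counts, not geodesic pixel area;
  on mid-latitude grids of modest extent the difference is small, and
  the classes themselves are defined by pixel quantiles.
- The per-zone test treats zones as fixed, ignoring that the zonation
  was estimated from the same climate data (not the same occurrence
  data, so the preference test's null is unaffected in practice).
- Accessible-area (M) polygons are consumed, never constructed; deriving
  M from dispersal simulations is out of scope.
- The CLI reads whole daily stacks into memory; multi-decade continental
  grids would need a chunked reader.
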