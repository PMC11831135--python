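# Methods

This note documents the statistical procedures implemented in `coalcrop`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Exposure construction

Wind octants denote the direction the wind blows **from** (meteorological
convention). This is forced by the identification logic: a station due
north of a point pollutes it on days with northerly wind at the station,
and that configuration must classify as *upwind*. Octant windows are
45° wide, half-open, closed clockwise at the lower edge
([center − 22.5°, center + 22.5°)), so a bearing of exactly 22.5° is NE
and 337.5° is N; any fixed tie rule would do, this one is stated and
tested by exhaustive enumeration.

Distances use the haversine formula on a sphere of radius 6371.0088 km;
bearings are great-circle initial bearings rather than planar
approximations, because at 100-km scale and ~20° latitude the planar error
is not negligible near band edges. Distance bands are half-open
[10k, 10(k+1)) km; a station at exactly 100.0 km contributes nothing.

The directional category of a wind octant relative to the point→station
bearing octant is the circular offset min(|i−j| mod 8, 8−|i−j| mod 8):
0 = upwind through 4 = downwind. The five per-band exposure regressors
are raw GWh totals, unscaled. By construction they conserve generation:
their sum equals the in-band stations' seasonal generation (asserted to
1e-9 relative in the tests), and exposure is additive over stations, which
is what makes the per-station damage decomposition exact.

The fleet is assumed fixed over the analysis period; commissioning and
retirement are out of scope, so the per-band station count — and hence the
single-station eligibility filter — is time-invariant.

## The band regressions

Each (season type, band) model absorbs point and state–season fixed
effects by alternating projections, sweeping unit and group means until
every within-group column mean is below 1e-10 (dummy-variable OLS is kept
only as a test oracle; the two agree to 1e-8 relative on small panels).
Weather enters linearly in seasonal mean temperature and seasonal total
precipitation; a switch adds quadratic terms. The fitting sample for band
b is restricted to points with exactly one station in band b, the
confounding filter of the base design; rows with zero in-band stations are
excluded from fitting but still receive (zero) attribution.

The covariance of the slope estimates is the cluster-robust sandwich over
state–season clusters with small-sample factor G/(G−1)·(N−1)/(N−K), where
K counts slopes plus absorbed fixed-effect degrees of freedom, and
confidence intervals use a t distribution with G−1 degrees of freedom.
With every observation its own cluster this reduces to the
heteroskedasticity-robust sandwich up to the stated factor.

A structural identifiability edge discovered during development: if every
point of some cluster is exposed to the same single station at band b, the
five category totals sum to a *cluster-level constant* (the station's
seasonal generation), which the state–season effects absorb — the design
is then exactly singular. Real fleets, with many stations per state, do
not produce this; the generator defaults place ~2 stations per state.
Rank-deficient designs raise an error naming the offending columns; in the
bootstrap they cause the iteration to be skipped and counted, with a hard
failure if more than 5% of iterations skip.

## Attribution

Coal-attributable NO₂ at a point-season is the sum over all ten bands of
the fitted directional coefficients times the **full** (unfiltered)
exposure — multi-station bands included, since the regressors are totals
over all in-band stations. All coefficients are used, significant or not,
and negative attributable NO₂ is not truncated: with the directional
regressors mechanically anticorrelated within a season (the days sum to
the season length), small negative downwind point estimates are expected
and are interpreted mechanically, not causally. The counterfactual column
is observed NO₂ minus attributable NO₂, with no renormalization. The
per-station decomposition applies the same coefficients to each station's
own exposure contribution and therefore sums exactly to the total.

## Damages

The yield change from removing attributable NO₂ Coal at a point with
greenness NIRv is (NIRv + Coal·β − 0.007)/(NIRv − 0.007) − 1, linear in
Coal, using NO₂→NIRv coefficients taken as external constants: 0.0006
(SE 0.0001) for monsoon rice, 0.0007 (SE 0.0002) for winter wheat, and the
0.007 bare-soil NIRv baseline. Points with NIRv ≤ 0.007 make the
denominator nonpositive; they are excluded from yield and output
arithmetic with a logged count (the generator never produces them, but
real data can).

State output gains scale reported state output by the ratio of the
cropland-fraction-weighted attributable-NIRv sum to the
cropland-fraction-weighted (NIRv − 0.007) sum over **all** of the state's
cropland points, not only those within 100 km — using the within-100-km
subset in the denominator would overstate gains. Station damages apply the
same formula to the per-station attribution and are summed across states,
so cross-border effects are counted and station damages aggregate exactly
to state totals.

Monetization: US$600/ton rice, US$350/ton wheat, VSL US$120,000, all
outputs in USD with no currency conversion. Seasonal damage intensity
divides a season's damages by that season's generation; annual intensity
divides combined rice+wheat damages by the year's total recorded
generation. In synthetic worlds generation is recorded only during the two
crop seasons, so "annual" generation means the year's recorded total; with
full-year generation data the same code yields the calendar-year ratio.

## Bootstrap

Uncertainty in attributable NO₂ and everything downstream is estimated by
a state–season cluster bootstrap (default 2,500 iterations per season
type, 95% percentile intervals). Each iteration draws the G observed
state–season clusters with replacement, relabelling each drawn copy as a
distinct cluster so that G stays constant and demeaning/clustering treat
copies separately; dataset size still varies because clusters differ in
size. After the single-station filter, all ten band models are refit, the
NO₂→NIRv coefficient is drawn once per iteration from its Gaussian (it is
a single national parameter, so a per-point draw would understate its
contribution), and four quantity families are evaluated on the full,
non-resampled data: state-mean attributable NO₂, cropland fractions by
yield-gain bin (<1%, 1–5%, 5–10%, ≥10%), state output gains, and station
damages. Intervals are plain percentiles (2.5th/97.5th), not BCa, by
design.

The bootstrap loop uses two exact algebraic shortcuts, both asserted
against the reference path in the tests: per-band panels are pre-indexed
by cluster so a refit is a row-block concatenation plus demeaned OLS, and
every downstream quantity is a fixed linear map of the 50 directional
coefficients, precomputed once as aggregation matrices.

## Policy stage

Stations with both mortality and crop intensity estimates are ranked by
the objective's intensity — monetized mortality (deaths/GWh × VSL), annual
crop damages per GWh, or their sum — and selected greedily until the next
station would push cumulative generation past the budget (default 10% of
total annual generation). Selection stops at the first over-budget
station: no fractional retirement, no skipping ahead to smaller stations;
this is a deliberately conservative reading of "select until they
cumulatively account for" the budget. Ties break by station id. The
seasonal variant treats each station×season as a separate opportunity,
assumes mortality intensity uniform over the year, and still measures the
budget against total annual generation.

Crop benefits are credited to every selected station regardless of the
ranking objective. One consequence of the stop-before-exceed rule worth
knowing: with heterogeneously sized stations, the crop objective can yield
*lower* crop benefits than the mortality objective — if the crop ranking's
top station alone exceeds the budget the selection is empty, while the
mortality ranking may select several small stations. The dominance
property (crop objective ⇒ maximal crop benefits among objectives) holds
when stations are equally sized, and that is the form the test suite
asserts.

The benefit range attached to a scenario sums the selected stations'
2.5th-percentile crop damages with the lower mortality estimates (and the
97.5th percentiles with the upper estimates). It is a range of sums of
bounds, not a prediction interval, and is labelled accordingly.

## The synthetic world

The generator emulates the statistical structure the estimator relies on,
not Indian geography. Defaults (the conditions used throughout the tests):
5 years (2018–2022) of paired monsoon and winter seasons, 2,000 cropland
points, 8 stations, a 18–26°N × 78–88°E box split into 4 longitude-band
states (20 state–season clusters per season type). Seasonal NO₂ is built
additively: true directional coefficients (β_up = 0.02/(1+band)
μmol m⁻² GWh⁻¹, category multipliers 1.0/0.6/0.3/0.15/0.05 from upwind to
downwind, mirroring the qualitative gradient of the estimated effects) ×
the same exposure construction the estimator uses, plus weather terms
(0.2 per °C, 0.005 per mm), i.i.d. Gaussian point effects (sd 3 μmol/m²
around a 25 μmol/m² baseline), state–season effects (sd 2), and noise
(sd 1). Wind octant probabilities are Dirichlet-drawn per station and
re-perturbed each season (concentration 50), which is the source of the
identifying year-to-year exposure variation. Generation is an AR(1) load
factor (mean 0.65, autocorrelation 0.7, sd 0.12) on a station capacity of
8–24 GWh/day with 3% outage days. NIRv is uniform on (0.05, 0.25),
independent of NO₂, since the NO₂→NIRv coefficient is an external
constant, not something the pipeline estimates. Crop output per
state–season is uniform on 2–12 Mt (rice) / 1–10 Mt (wheat); mortality
intensities are lognormal around 0.02 deaths/GWh. Sixty percent of points
are placed around stations with uniform (not area-uniform) radius so inner
distance bands retain usable sample sizes. All streams derive from one
master seed via `numpy` SeedSequence spawning, so every table is
independently reproducible.

Where the real marginal distributions are unknown (generation, wind,
output levels), these choices are conveniences, not claims about the data.

## What the validation shows

* Noiseless identity: with noise, fixed effects and weather zeroed and
  stations spaced >200 km (so no point sees two stations), the estimator
  recovers the generating coefficients to ~1e-14 — the plumbing is exact.
* Frequentist calibration: across 200 default worlds, the 95% clustered
  CIs for β_up cover the truth ≈91% of the time (asserted within 88–99%),
  the familiar mild undercoverage of cluster-robust inference at G = 20;
  the estimated upwind coefficient exceeds the downwind one in >95% of
  band fits.
* Bootstrap calibration: intervals are exactly degenerate in the noiseless
  zero-SE limit; on stochastic worlds with 40 clusters (8 states — chosen
  because percentile cluster-bootstrap validity is asymptotic in the
  number of clusters, and the emulated study has on the order of 150
  state–season clusters), reduced-rep intervals (200 iterations × 50
  worlds) cover the true state-mean attributable NO₂ ≈90% of the time
  (asserted within [85%, 100%]).

Passing these tests shows the estimator, intervals and accounting are
implemented correctly under the model's own assumptions. It does not show
that the assumptions hold in real data: the generator has no spatially
correlated noise fields, no co-located non-coal NO₂ sources (the main
confounding risk the single-station filter and fixed effects mitigate but
cannot eliminate), no NO₂–NIRv feedback, and no seasonal generation
trends correlated with pollution.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: 200 worlds for CI coverage, 50 worlds × 200 iterations for
bootstrap coverage, 1,200–2,000 points per world. Demeaning tolerance is
1e-10 with a 1,000-sweep cap; singular designs raise rather than silently
pseudo-inverting; percentile computation uses linear interpolation between
order statistics; CSV output uses 17-significant-digit floats and reading
uses round-trip parsing, so write→read is lossless.
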