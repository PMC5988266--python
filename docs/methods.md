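# Methods

`hydrurga` reimplements a year-round biologging analysis for a pinniped
tracked with archival light/immersion loggers: light-level geolocation
with a Bayesian movement-constrained posterior, haul-out segmentation from
salt-water immersion counts, and penalized additive binomial models for
habitat association and hourly haul-out probability.  Everything runs
end-to-end on synthetic data whose generating structure matches what the
analysis assumes, with exported ground truth, so each stage's estimator
can be checked against a known world.

## Light-level geolocation (threshold method)

A GLS logger samples light every 60 s and stores the maximum per 10-min
window on a clipped integer scale.  A *twilight* is the interpolated
moment the recorded light crosses a calibrated threshold; for a twilight
zenith angle `z` the sunrise equation

    cos H = (cos z − sin φ sin δ) / (cos φ cos δ)

links the half-day hour angle `H` to latitude `φ` and solar declination
`δ`.  Longitude comes from the timing of the rise/set midpoint against
solar noon (equation of time applied); latitude from day length.  Solar
geometry uses the NOAA low-accuracy formulae (verified to ≤0.2° zenith
against an independently coded Astronomical Almanac algorithm), ample for
a 10-min light cadence.

Two conventions matter at the ±0.25°-longitude level:

* **Max-of-window timestamp correction.**  The logger stamps each window
  at its start but stores the window maximum, which on a rising limb is
  attained at the window's end.  Rise crossings are therefore shifted by
  +9 min (window length minus one sample).  Without this the rise/set
  midpoint is biased ~5 min ≈ 1.25° of longitude.
* **Shading filter.**  Hauled-out animals cover the sensor; dark runs
  shorter than 2 h flanked by bright windows (and bright blips < 30 min)
  are flagged `suspect_shading` and never emitted as twilights.

**Calibration** grid-searches (zenith, threshold) to minimize the RMS
residual between detected and predicted twilight times at a known site.
The pair is identified only up to the light transfer curve's trade-off
line — every threshold has a zenith that predicts identical crossings at
a fixed site — so the recovered pair is reported as *a* self-consistent
calibration, not *the* generating one.  Position recovery is unaffected:
on a noiseless 30-day fixture the calibrated pipeline recovers the site
to ~0.02° latitude and ~0.07° longitude.

Latitude from day length degenerates near the equinoxes (day ≈ 12 h at
all latitudes); positions within ±10 days of an equinox are flagged and
their observation error inflated (default ×3) in the movement model.

## Movement posterior

One location state per clean twilight; days with a known location (the
animal observed at the deployment site) are fixed and never proposed.

*Observation model*: the signed twilight error in minutes (positive
toward darkness — shading can only delay a dawn or advance a dusk) is
shifted log-normal: `ε + shift ~ LogNormal(log scale, sdlog)` with
defaults scale 8 min, shift 2 min, sdlog 0.7.  The family and defaults
are package choices; nothing in the source analysis pins them.

*Movement model*: the speed between successive states is log-normal with
arithmetic mean 1.0 km/h and SD 0.9 km/h on the natural scale (values
from comparable satellite-tracked animals; the source states "variance"
with km/h units, which we read as an SD).  Internally the transition
kernel is the **proper random-walk density**: log-normal speed × uniform
heading, i.e. the speed log-density minus log(distance) (the polar-
coordinates Jacobian), plus the log cos(lat) area term of the lon/lat
parameterisation.  This matters: with the bare speed density the implied
step prior is weighted by the area element (∝ distance) and posterior
speeds inflate by ~80% on a 1 km/h synthetic world; with the proper
kernel the posterior-mean implied speed recovers the generating value
(0.93 km/h on the 200-step acceptance experiment).

*Sampling* is Metropolis-within-Gibbs with per-state Gaussian proposals
in km (scales adapted during burn-in toward 0.2–0.4 acceptance), sweeping
forward in time on odd passes and backward on even, plus block-translation
proposals that shift contiguous runs of free states by a common offset.
The block moves are essential for mixing: residency phases behave as
stiff clusters under the transition prior, and without them the
prescribed budgets (4 chains × 5000 iterations, 50% burn-in) leave the
envelope badly under-dispersed.  Zero-distance steps are floored at
0.01 km/h so repeated locations keep finite density.

*Initialisation*: per-day threshold positions, fixes substituted,
equinox/polar gaps interpolated, speed-capped smoothing toward neighbour
midpoints, and a coarse 2° grid likelihood scan to repair any state left
with zero likelihood.

*Polar day*: runs of days with no usable twilight contribute only the
movement prior; for covariate extraction the location is pinned to the
last known position before the run (inter-state gaps > 48 h are never
interpolated across).

*Derived products*: per-chain mean paths (the habitat "use" ensemble),
great-circle intermediate locations (k per segment, each weighted
dt/k hours), and time-spent grids (default 1000 simulated paths,
densified, binned, normalized to unit mass, optional per-cell quantiles).

Known limitation: the uniform-heading prior is mis-specified for strongly
directed migration legs; there the posterior lags the truth slightly and
per-draw implied speeds inflate to ~1.3 km/h on a 1 km/h world.  The
speed-recovery experiment therefore uses the central-place residency
world (the generator default), which the prior matches.

## Haul-out segmentation

Immersion counts (0 = dry, 200 = fully wet per 10-min window at one 3-s
conductivity test every 3 s) are shifted by −200 so haul-outs appear as
"dives" at −200.  A bout runs from the first fully-dry window to the
first subsequently wet one; bouts shorter than 1 h are discarded; runs
interrupted by record gaps > 30 min are flagged `truncated` and excluded
from duration statistics by callers that need clean durations.  Hourly
states are clock-aligned UTC bins [h:00, h+1:00), hauled-out iff the hour
overlaps any bout.  The summary reproduces the standard per-trip report
(total days, proportion of span, max/median bout, inter-bout intervals,
longest continuously-wet period); a recorded-hours-only proportion is
also reported since the span-based denominator is ambiguous when the
record has gaps.

## Penalized additive binomial models

A compact GAM engine shared by the habitat and activity analyses:

* cubic regression splines in knot-value coordinates (natural cubic
  interpolation design, integrated-squared-second-derivative penalty);
  cyclic variant matching value and two derivatives at the period ends;
* shrinkage: the penalty's null space (the line) receives a small
  eigenvalue (0.1 × smallest positive) so heavy penalization can remove a
  term entirely;
* by-factor smooths replicate a basis per group level with one *shared*
  smoothing parameter (a deliberate simplification; per-level parameters
  would multiply the search cost at no benefit for desk-scale designs);
* random intercepts as ridge-penalized group dummies, nesting handled by
  concatenating factors (trip within tag);
* links: logit, and cloglog for the rare-outcome hourly haul-out series;
* fitting: penalized IRLS with step-halving (penalized deviance is
  non-increasing), convergence at relative deviance change < 1e-8;
* smoothing parameters: coordinate descent on log10 λ over a grid with
  golden-section refinement, scoring by a Laplace-approximate REML
  (GCV available).  Smooth-term p-values are Wald-type approximations
  and labelled as such.

AIC uses effective degrees of freedom: `AIC = −2ℓ + 2·tr((XᵀWX+S)⁻¹XᵀWX)`.
With a single shared λ multiplying both curvature and shrinkage penalty,
a smooth fitted to pure-line data keeps modest residual wiggle (edf ~3,
matching mgcv's behaviour on the identical setup) — the fitted curve is
still linear to within a few percent of its range.

## Habitat use–availability

"Use" rows: 100 chain-mean paths, the covariate at each time step
averaged over the ensemble (location error propagates into the design).
"Availability": 10 correlated-random-walk nulls resampling the source
step lengths with replacement, headings uniform plus a weak drift
(weight 0.3) toward the source's net displacement bearing — the minimal
reading of a null "based on the mean trajectory and step distances".
SST is the weekly slice with monthly fallback; hours hauled out on land
are discarded.  The candidate ladder is the standard nine: each covariate
linear, each as a shrinkage smooth, and the three pairwise linear sums,
ranked by log-likelihood.  Covariates too degenerate for a spline (ice
concentration on a track that never reaches the pack) degrade that
candidate to a linear term.

## Hourly haul-out models

Cloglog penalized additive fits of the hourly state on: cyclic hour of
day (period 24, optionally by month), cyclic week of year (period 53,
optionally by tag; month and Julian day as alternatives), latitude,
distance to the nearest land polygon or monthly ice-edge latitude
(haversine on R = 6371.0088 km; points inside land or poleward of the
edge are at distance 0 — pack ice is haul-out substrate), and lagged
states as linear binary terms.  The candidate family mirrors the
selection table of the source analysis (12 structures: lag depth,
smoother grouping, seasonal-term alternatives), ranked by AIC with
stable ties broken by fewer effective parameters.

Recovery behaviour worth knowing: because the model conditions on lags,
the hour smooth estimates the *bout-start hazard* phase, not the raw
state proportion peak (which trails it by roughly the mean bout length);
and lagged-state coefficients carry bout-age information only when the
bout-length law is non-memoryless — a geometric continuation yields a
null lag3 no matter the sample size.

## Synthetic world

Defaults are the stated study conditions: deployment site 54.01°S
38.05°W; per-step speeds log-normal with arithmetic mean 1.0 / SD
0.9 km/h at 12-h steps; immersion counts 0–200; haul-out bouts from an
hourly hazard with diel and seasonal cosines, per-hour persistence
0.75, minimum bout 1 h; light a logistic function of solar altitude on
an integer 0–64 scale (a BAS-logger-like convention — the true sensor
scale is undocumented), anchored so light crosses the configured
threshold exactly at the configured zenith.  Environment grids are
analytic stand-ins sharing one lon/lat grid: signed depth proportional
to distance from a synthetic coastline, SST increasing equatorward with
a seasonal cosine, ice concentration ramping poleward of a monthly edge
latitude (southern-hemisphere convention).

What the generator does *not* emulate: dive-induced light attenuation,
weather/cloud noise structure, behaviourally switching movement states,
real bathymetry or ice dynamics, tag clock drift.  A green recovery test
therefore establishes estimator correctness under the stated model, not
robustness to the full messiness of field data.

## Numerical choices

* Sphere radius 6371.0088 km everywhere; longitudes in [−180, 180).
* Twilight crossing interpolation linear in light between bracketing
  windows; equinox window ±10 days.
* MCMC: proposal lon-step conversion frozen at the initial-path latitude
  (exact proposal symmetry); −∞ log-densities floored at −1e8 so chains
  can leave infeasible starts; thinning to ≤ 200 retained draws/chain.
* PIRLS: 1e-9 ridge for solvability; probabilities clipped to
  [1e-10, 1−1e-10]; cloglog linear predictor clipped to [−30, 3.5].
* Distance to land: boundaries densified to ≤ 0.04° (< 5 km) before the
  nearest-vertex search.
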