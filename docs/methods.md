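# Methods

`flytrack` reconstructs the annual movements of small migratory birds
from archival light-level geolocators and derives spring-migration
phenology (departure, arrival, distance, rate, stopover use) and
group-level statistics from them.  This note documents the models, the
free parameters, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Solar model and the threshold method

Solar declination and the equation of time come from the NOAA
low-precision closed form (a Fourier series in the fractional year),
accurate to ~0.3° in declination and ~0.5 min in the equation of time.
Light-level geolocation carries 0.5–2° of intrinsic error, so an
ephemeris would add nothing.

A *twilight* is the instant the light trace crosses a fixed threshold
(sunrise upward, sunset downward), with the crossing time linearly
interpolated between samples — the sampling interval (2–10 min),
not the interpolation, dominates the timing error.  Candidate dark
(or light) spells shorter than a configurable minimum (default 120
min) are merged before events are emitted, which rejects shading
artefacts.

The *threshold method* inverts a sunrise/sunset pair: longitude from
the twilight midpoint against apparent solar noon; latitude from day
length and declination at the calibrated zenith angle.  Two numerical
points deserve note:

- At zenith ≠ 90° the day-length equation has **two** latitude roots.
  The spurious root lies near a pole; the equator-nearer root is
  selected.  This is valid for the study domain (|lat| ≤ 45°) and
  would need revisiting for polar applications.
- The equinox degeneracy is detected by **conditioning**, not by a
  12-hour day-length test: a fix is flagged `latitude_unreliable` when
  |∂lat/∂daylength| exceeds 2° per minute, i.e. when minutes-scale
  twilight noise maps to multi-degree latitude error.  A 12-h rule is
  kept only at zenith ≈ 90°, where it is equivalent; at a calibrated
  zenith of ~96° the light day exceeds 12 h everywhere near the
  equinoxes and a 12-h light day can occur at perfectly
  well-conditioned latitudes.

## Calibration

While the bird is at the (known) capture site, each observed twilight
is compared with its prediction.  Shading can only delay a sunrise or
advance a sunset, so twilight delays are one-sided and modelled as
log-normal (minutes).  The zenith angle is anchored at the *maximum*
observed crossing zenith — the least-shaded twilight — and then
shifted by a profile-maximum-likelihood estimate of that twilight's
own residual delay (the additive shift that makes the delay sample
most log-normal, bounded above by the median delay).  A median-based
zenith would absorb the typical delay and sit 1–2° low, biasing every
downstream position.  Delays are floored at 0.01 min; a degenerate
(noise-free) delay sample sets `err_sdlog` to a floor of 0.05 with a
warning.  Parameter recovery at 60 twilights: zenith within ~0.2°,
log-normal parameters typically within 10–20%.

## Track posterior

Daily locations are sampled by a Metropolis scheme targeting

    log p(x_1..n) = Σ_d twilight loglik(x_d) + Σ_d speed prior(x_d, x_{d+1}) + mask(x_d)

- **Twilight likelihood**: per day, the log-normal log-density of the
  sunrise and sunset delays at the candidate position, −∞ where a
  predicted twilight does not exist (polar) or a delay is
  non-positive.
- **Speed prior**: great-circle speed between consecutive daily
  positions, divided by a maximum (default 80 km/h), clamped into
  (0, 1), scored by a beta(2.2, 2) density.  The shape defaults are
  deliberate conventions of this package (no published values exist
  for this system); they weakly discourage both teleportation and
  perfect stasis.
- **Land mask** (optional): −∞ off the supplied polygons.  The mask is
  applied to *all* days, not only stationary ones, because
  stationarity is unknown while sampling.

Proposals are Gaussian random walks (default SD 0.5°), latitude
reflected at the poles, longitude wrapped.  Days are updated in a
checkerboard (even given odd, then odd given even), which leaves the
single-site conditionals exact and vectorises across chains and days.
Protocol: 3 runs × 3 chains × 5,000 iterations by default; the first
runs are burn-in, each run initialised at the previous run's median
daily locations; the final run is thinned by 2.  The chain is
initialised from threshold fixes with the observed twilights pulled
inward by the typical delay exp(meanlog) — the raw threshold fix sits
on the boundary of the delay support, where the log-normal density
vanishes.  Sampling is deterministic given the seed; an acceptance
rate outside [0.05, 0.80] emits a warning.

For a stationary bird the *pooled* site estimate (median of daily
medians) is accurate to ~0.2° latitude / ~0.1° longitude under
realistic noise; individual daily medians scatter by 1–2° of latitude
because a single day's twilight pair is genuinely that uninformative.

## Stationary-period segmentation

A greedy forward pass over the daily posterior summaries keeps a
running mean of the segment's daily medians and its mean daily 95%-CrI
half-width; an incoming day breaches when its median departs from the
running mean by more than `z_break` (default 2.0) pooled half-widths
on either axis.  Two refinements:

- **One-day confirmation**: a breach opens a new segment only if the
  following day also breaches; an isolated excursion day is absorbed.
  Without this, one noisy day can split a two-month winter period and
  shift the inferred spring departure by weeks.
- **Equinox option** (off by default): within ±15 days of an equinox
  only longitude is tested.

Segments of at least `min_days` (default 2) become stationary periods,
pooling the samples (or summaries) of their days; shorter segments
become movement days.  `z_break` is the module's central free
parameter.  The period count is monotone non-increasing in `z_break`
in the regime the statistic targets — CrI width dominating day-to-day
median jitter, which is what MCMC posteriors produce.  When the jitter
is comparable to the CrI the stationary-period count is *not* monotone
at small `z_break` (every day breaks, segments fall under `min_days`
and become movement), which is why the suite tests monotonicity in the
CrI-dominated regime.

## Phenology rules

Operating on the schedule (all day arithmetic inclusive of both
endpoints, the convention the per-individual table implies):

- **Winter start**: first stationary period of ≥ 30 days after the
  deployment season (a leading stationary period opening the record is
  treated as the deployment season unless an explicit search window is
  given).
- **Spring initiation**: end of the first ≥ 30-day period not followed
  by another ≥ 30-day period.  Winter duration runs from winter start
  to initiation; the number of winter sites counts the ≥ 30-day
  periods in between.
- **Arrival**: first post-initiation date whose daily longitude 95%
  CrI contains the breeding-site longitude.  At the Argentinian sites
  the route runs due north of the breeding site, so the longitude
  criterion fires weeks early; arrival there is floored by the yearly
  census first-observation date.  No qualifying date → missing, which
  propagates to duration and rate.
- **Distance**: great-circle distance (sphere, R = 6,371 km) from the
  median of the last winter period to the breeding site.  Rate =
  distance / duration.  Stopovers are the stationary periods strictly
  between initiation and arrival.
- **QC**: within a site, a record whose rate exceeds twice the
  next-fastest rate is flagged and excluded from group statistics (an
  artefact of arrival-date uncertainty near the equinox).

## Statistics

Group summaries are arithmetic means and sample SDs (n−1), missing
values dropped per variable; date variables are summarised on
day-of-year (Jan 1 = 1) in each record's own calendar year.  Linear
models are Gaussian OLS with treatment coding (DF as the reference
breeding site); model reduction is backward elimination by
likelihood-ratio χ² tests (drop the removable term with the largest
p > 0.05; interactions are removed before the main effects they
contain).  The correlation test is Pearson's r with the exact
t = r√(n−2)/√(1−r²) on n−2 df.  The two-group comparison is a Welch
two-sample t test — the original analysis never names its test
statistic, so Welch is this package's labelled choice.  All p values
two-sided; no multiple-testing correction is applied (none is applied
in the analysis being mirrored).

The duration and arrival site models are *not* asserted against the
published coefficient tables: their final covariate sets (tarsus,
wing × tail interactions, sex handling) are not recoverable from the
summary data alone.  The distance and initiation models recompute
exactly from the per-individual table and are asserted.

## Synthetic data: what it emulates, and what it does not

The generator builds annual itineraries matching the study system:
breeding at one of the four sites, fall migration to a winter range
near 2–3° N, one to a few winter sites, and a spring migration of
~2,600–5,100 km with 0–5 stopovers over 16–57 days.  Stationary legs
are fixed points; transit days are great-circle interpolated, with
stopovers placed at the flown fraction of transit time so each flight
day covers a comparable distance (daily steps are checked against an
800 km/day ceiling).  Light is a logistic function of solar zenith
(steepness 0.5°) around a truth zenith of 96°, clipped to the sensor
range; sunrise is delayed and sunset advanced by independent
log-normal draws (default meanlog log 3 ≈ 3 min median, sdlog 0.5 —
chosen as typical open-habitat twilight error); shading events
(Poisson, default 0.2/day, 10–60 min) zero the light.

Not emulated: weather- and habitat-driven shading structure
(correlated, diurnally biased), sensor clipping nonlinearity beyond a
hard max, movement within a day, longitude-dependent twilight error,
and real coastline land masks.  Passing recovery tests therefore
demonstrates the correctness of the estimation chain under its own
error model, not field performance on real tags — the published
per-individual table, which the statistics layer reproduces exactly,
is the only real-data surface in the package.

Problem sizes used by the test-suite and reproduction script —
30-day calibration and stationary-recovery simulations, a ~330-day
end-to-end scenario sampled at 1,500 iterations × 2 chains × 3 runs —
are the package's validation defaults; the full 5,000 × 3 × 3 protocol
is the analysis default.

## Known limitations

- Latitude root selection restricts use to |lat| ≲ 60°.
- Twilight-pair days are keyed to the local civil date of the light
  period's midpoint; behaviour at |lon| near 180° is untested.
- The sampler factorises the behavioural model pairwise between
  consecutive daily positions; movement between the twilights of a
  single day is not modelled.
- Manual twilight editing is supported only as a per-event exclusion
  flag; no automatic outlier editing is applied by default.
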