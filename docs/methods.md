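# Methods

`neodem` reconstructs the spatio-temporal dynamics and demography of an
expanding population — the motivating case is the spread of early farming
across Europe and the Near East — from nothing but a table of radiocarbon
determinations with coordinates and period labels. This note documents the
models, the numerical choices, and what the synthetic validation does and
does not establish.

## Calibration model

A determination (CRA, σ_lab) is related to calendar age t (cal BP) through a
calibration curve (μ(t), σ_curve(t)). We use the standard intercept-free
Gaussian model with variances added in quadrature:

    mass(t) ∝ exp( −(CRA − μ(t))² / 2(σ_lab² + σ_curve(t)²) ) / √(σ_lab² + σ_curve(t)²)

normalised to unit mass on a 1-yr calendar grid. Curves supplied in the
IntCal `.14c` dialect are linearly interpolated from their native spacing to
1 yr; calibration is insensitive to the native spacing (modes move ≤ 1 yr
between a 5-yr export and the 1-yr original — tested). Choices:

* **Grid step 1 yr.** Mode extraction feeds the 100-yr hull stratification;
  working far below that resolution makes the hull series independent of
  grid artefacts.
* **Support truncation.** Total tail mass 10⁻⁵ is trimmed (half per tail)
  and the remainder renormalised, bounding memory without measurable effect
  on any downstream statistic.
* **Mode ties break toward the older age.** Deterministic, and consistent
  with the first-arrival logic of front tracking.
* All ages are cal BP (before 1950), larger = older. No BC/AD conversion
  exists anywhere in the package.

`uncalibrate` inverts the model for simulation: CRA = μ(t) + N(0,
√(σ_curve(t)² + σ_lab²)). The curve error enters **once**, at this draw;
recalibration of a simulated CRA uses the same likelihood as a real date and
does not double-count it.

Two evaluation paths exist: a dense per-date path (used for observed SPDs
and anything needing per-bin components) and a banded scatter-add path for
ensemble simulation that evaluates each date only within ±5 combined
standard deviations of its inverted calendar position (requires a strictly
increasing μ; agrees with the dense path to ~10⁻⁶ relative — tested).

## Front tracking

The cumulative convex hull of all Neolithic-labelled points whose calibrated
mode is at least τ is computed for each 100-yr boundary τ from 12,000 down
to 4,000 cal BP. Hulls are nested by construction and areas non-decreasing.

* **Area metric.** Points are projected with a spherical Lambert azimuthal
  equal-area projection centred on the point cloud before hull and area
  computation; areas are km². (An external projection library is not a
  dependency; the forward/inverse Snyder formulas are implemented in
  `neodem.geo` and round-trip tested.)
* **Pulse detection.** The per-step fractional area growth ΔA/A flags a
  pulse start at the older boundary of the first super-threshold interval
  following at least `pause_len` quiet steps, and an end once growth stays
  sub-threshold for `pause_len` steps. Defaults: `growth_frac = 0.05` per
  step, `pause_len = 2`. A candidate pulse whose *cumulative* area gain is
  below `min_growth = 0.25` (relative to the area at its start) is
  discarded: with realistic calibration noise, a handful of outlier modes
  can push isolated steps over the per-step threshold, and such blips are
  dating noise, not dispersal. Real dispersal rings added ≥ 40% area in
  every configuration examined, so the cleanup is far from the signal. All
  three knobs are config-exposed.
* **Regionalisation.** Region 0 is the hull in place when the first pulse
  starts; region k is the geometric difference of the hulls at the ends of
  pulses k and k−1. Slivers under 1 km² are cleaned. Optional cultural
  split polylines bisect target regions (left/right of the line's direction
  of travel). Boundary points are assigned to the earlier-pulse region: the
  front defines first arrival.

## SPDs, binning, growth rates

Dates from one site whose CRAs chain within h = 200 ¹⁴C yr form one
site-phase bin (single linkage); each bin contributes the arithmetic mean of
its members' calibrated densities, so a raw SPD's total mass equals the
number of site-phases. Rescaling (`per-bin` or `unit-area`) makes SPDs
comparable across regions.

Taphonomic correction divides the SPD by the power-law survival curve
n(t) = 5,726,442 · (t + 2,176.4)^(−1.3925309) and renormalises to preserve
total mass. Since survival *decreases* with age, the correction inflates
older ages and therefore lowers fitted growth rates.

Growth rates come from nonlinear least squares of C·exp(−r·t) on the SPD
curve itself (t in cal BP, so r > 0 means growth toward the present) — not
log-linear regression, which near-zero cells bias. The amplitude is profiled
out analytically, leaving a 1-d bounded search over r ∈ [−0.02, 0.02]
(tolerance 10⁻¹²; exact exponential inputs are recovered to < 10⁻⁵ in
rate-percent). Standard errors are a 200-replicate bootstrap over site-phase
bins, computed as one multinomial-weight matrix product. Rates are reported
both as fractions per year and as the conventional %/yr (100·r).

**Edge handling.** Cells within `edge_margin = 200` yr of a chronological
bracket lose probability mass to truncation; growth fits exclude them. The
validation studies use a 300-yr inset (≈ 3 maximal combined standard
deviations of the toy-curve error model) for the same reason.

## The Monte-Carlo SPD test

The null hypothesis is that a region's record continues its Mesolithic
exponential trend. The null is fitted **only** to Mesolithic-period dates in
[12,000, T_neo], where the Neolithization date T_neo defaults to the mode of
the region's oldest Neolithic date (config-overridable, e.g. by pulse
start). Each of `n_sim = 1000` (500 in the studies) simulations draws as
many calendar ages from the fitted truncated exponential over the full test
window as the observed record has site-phases, uncalibrates them with lab
errors resampled from the observed pool, recalibrates, and sums as singleton
bins.

* **Envelope.** Each simulated SPD is first scaled to the observed total
  mass; the pointwise 2.5%/97.5% quantiles form the 95% band, and contiguous
  runs of the observed SPD outside it are recorded with direction.
* **Global p-value.** Observed and simulated curves are z-scored against the
  ensemble mean and SD; the statistic is the summed |z| at points outside
  the pointwise 95% band of the simulated z-curves; p = (1 + #{sims with
  statistic ≥ observed}) / (n_sim + 1), so p is never 0. The statistic is
  two-sided (excursions below the band count symmetrically). Zero-variance
  grid points are excluded and logged.
* By construction ~5% of the record sits outside a 95% envelope under the
  null; no automated false-positive screening is applied — excursion lists
  are meant to be read alongside the global p-value and the calibration
  curve.

Measured operating characteristics (recomputed by `scripts/acceptance.py`
and the acceptance tests, never hard-coded): the false-positive rate of the
global p at α = 0.05 over 200 null replicates, and the average pointwise
envelope coverage over 200 held-out null curves.

## Synthetic worlds

The generator emits the same CSV schema as real data plus row-for-row ground
truth. Farming spreads radially from an origin in pulses (speeds 0.5–2.5
km/yr); each pulse paints an annulus of first arrival (great-circle
distances; radially symmetric fronts are the natural test geometry for a
convex-hull method). Forager sites are scattered with ring-class densities
and exponential date intensity; three regimes govern arrival:

1. **Origin, carrying-capacity boost:** the same sites switch to a faster
   exponential rate at Neolithization (flagship default 2×10⁻⁴/yr over a
   10⁻⁴/yr Mesolithic background; the three-regime preset uses a
   quasi-stationary 3×10⁻⁵/yr background switching to 3.5×10⁻⁴/yr — the
   near-carrying-capacity forager picture, so the origin's trend change is
   an actual phenomenon rather than a marginal rate shift).
2. **Boom/bust rings (sparse foragers):** farming sites appear with the
   front at a multiplicative intensity boost that relaxes exponentially
   (e-folding `boom_relax`) toward a configurable floor once the front
   departs for the next ring — reproducing the staggered boom-preceded-by-
   a-drop pattern of a travelling front.
3. **Continuity rings (dense foragers):** existing sites adopt farming;
   period labels flip at arrival, intensity does not.

CRAs are drawn through a monotone toy curve (identity + 20-yr-amplitude,
1,100-yr-period sinusoid, 8-yr curve error) — wiggly enough that calibrated
densities are non-trivial, monotone so it is invertible. Lab errors are
uniform on a configurable range (≤ 150 ¹⁴C yr; a configurable fraction of
oversized errors can be injected to exercise the quality filter). Everything
is deterministic per seed; regeneration is byte-identical.

Two presets encode the two validation studies:

* `WorldConfig.pulse_world` — six pulses, every ring boom-type (the regime
  the travelling wave itself produces), ~3,000 dates, record concentrated at
  the front the way foundation phases dominate early farming chronologies,
  and an origin occupied from before the analysis window so the window opens
  on an established hull. Used for pulse-count/timing recovery.
* `WorldConfig.three_regime` — origin boost + two staggered boom rings + one
  continuity ring, ~1,500 dates, quasi-stationary forager background, origin
  Neolithized inside the window so its Mesolithic null window is non-empty.
  Used for the classification study, with regions taken from ground-truth
  rings (hull detection is validated separately by the pulse study).

**What the synthetic worlds do not emulate:** coastlines and topography
(fronts are isotropic), research-intensity bias between regions, taphonomic
thinning (available only as the correction, not as a generative process),
reservoir effects, and real-curve plateaus longer than the toy sinusoid's
wiggles. Passing tests therefore demonstrate the *machinery* — calibration,
geometry, statistics, seeded reproducibility — under a controlled world
model, not the archaeological correctness of any particular regional
reading.

## Regime classification

A region is classified from its test result and observed SPD. Not
significant at α = 0.05 → continuity (regime 3). Otherwise above-envelope
excursions merge into chains (gaps ≤ 250 yr); chains shorter than 150 yr,
or confined to the 500-yr edge-affected margin, are ignored as noise. A
chain *overlapping* the arrival era [T_neo − 1,500, T_neo + 300] marks a
front-arrival signal (overlap, not chain-start membership: merging can drag
a chain's start older than the window). Regime 1 vs 2 is then decided by
whether the record **busts**: the observed level near the young edge is
compared with the boom peak (the chain clipped to the arrival era) — below
0.8 of the peak is a boom-then-bust travelling-front signature (regime 2),
at or above it a lasting trend change (regime 1). Envelope-excursion
persistence alone cannot make this call: mass-matching against an
extrapolated null tends to push most of the post-arrival record above the
envelope in both regimes. A significant deviation with no arrival-era chain
is regime 1 if some chain persists to the young edge, else regime 3. On 50
three-regime worlds this rule classifies ≥ 80% of regions correctly and
reproduces the ring-ordered boom staggering (measured in the acceptance
suite); residual errors are marginal false booms in continuity rings
(p just under 0.05) and occasional underpowered origins.

## Problem sizes and defaults

The validation studies run at: 200 replicates × 500 simulations × 100 bins
(null calibration and coverage), 100 replicates × 500 dates (rate
recovery), 3 worlds × ~3,000 dates (pulse recovery), 50 worlds × ~1,500
dates × 500 simulations (regime study). These sizes give binomial/bootstrap
noise comfortably inside the asserted bands while keeping the whole suite
runnable on a laptop core in well under half an hour.

## Known limitations

* The pulse heuristic assumes pauses of at least `pause_len` hull steps;
  pulses separated by shorter pauses merge (the generator's default
  schedules keep pauses ≥ 400 yr).
* Pulse onsets are sharply datable only where the front carries a dating
  signal (regime 2). In continuity regions the first-date delay at newly
  reached sites lags the hull behind the true front by one or more steps —
  visible in the default mixed-regime world.
* `T_neo` estimated as the oldest Neolithic mode is biased old by
  calibration outliers; the classifier's onset window absorbs ±300 yr, and
  a config override (e.g. pulse start) is available.
* The MCSPD global p is computed against a band the simulations helped
  build; with 500+ simulations the resulting rank bias is far below the
  binomial noise of the calibration experiment.
* Convex hulls cannot represent non-convex fronts (coastline detours,
  riverine corridors); area pulses remain detectable, but ring differences
  then mix first-arrival zones.
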