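# neodem

Radiocarbon-based inference of dispersal dynamics and demography: calibrate
dates, track an expanding front with time-stratified convex hulls, detect
dispersal pulses, partition the study area into first-arrival regions, build
Summed Probability Distributions (SPDs), and test each region's record
against a Monte-Carlo exponential null model fitted to its pre-transition
(Mesolithic) dates only.

The package is aimed at archaeological demographers working with large
¹⁴C compilations — the motivating application is the spread of early farming
across Europe and the Near East — and at anyone who wants the statistical
machinery (SPD null-model testing, envelope construction, growth-rate
estimation) with a fully synthetic, ground-truthed validation path.

## The method in brief

**Calibration.** A determination (CRA, σ_lab) maps to a calendar density
mass(t) ∝ N(CRA | μ(t), σ_lab² + σ_curve(t)²) on a 1-yr grid, with the mode
stored per date. `uncalibrate` inverts the model for simulation.

**Front tracking.** For each 100-yr boundary τ in [12,000, 4,000] cal BP,
the convex hull of all Neolithic points with mode ≥ τ is computed on an
equal-area projection. Episodes where the hull area grows by more than a
threshold fraction per step, after a pause, are dispersal pulses; hull
differences at pulse ends partition the map into first-arrival rings, which
partition the date table into regions.

**SPD and null test.** Per region, dates chain into site-phase bins
(gap ≤ h = 200 ¹⁴C yr within a site); the SPD sums bin-averaged densities.
An exponential null C·exp(−r·t) is fitted to the region's **Mesolithic-only**
SPD up to its Neolithization date, then used to simulate ensembles of equal
size (draw ages → uncalibrate → recalibrate → sum). The observed SPD is
compared with the ensemble's pointwise 95% envelope, and a global p-value
ranks its summed out-of-band |z| statistic within the ensemble. Growth rates
are reported in %/yr, optionally corrected for taphonomic loss via
n(t) = 5,726,442 · (t + 2,176.4)^(−1.3925309).

**Synthetic worlds.** `neodem.synth` generates pulsed wave-of-advance worlds
(origin + annular rings, speeds 0.5–2.5 km/yr) under three demographic
regimes — carrying-capacity boost at the origin, staggered boom/bust along
the travelling front, continuity where foragers were dense — with
row-for-row ground truth, so every stage has a parameter-recovery test.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a three-regime world, calibrate, and test each ground-truth region
against its Mesolithic null:

```python
from neodem import pipeline
from neodem.config import RunConfig
from neodem.synth import WorldConfig, generate_world, regime_report

world = generate_world(WorldConfig.three_regime(seed=5))
cal = pipeline.calibrate_table(world.dates, world.curve)
label_of = dict(zip(world.truth.regions["ring"], world.truth.regions["label"]))
cal["region"] = world.truth.per_date["ring"].map(label_of)

cfg = RunConfig(seed=5, bracket_young=4_000, n_sim=500)
results = pipeline.test_all_regions(cal, world.curve, cfg)
for k, r in results.items():
    print(f"{k:8s} N={r.n_bins:4d}  p={r.test.global_p:.4f} "
          f"rate={r.fit_raw.rate_pct:.4f} ± {r.fit_raw.se_pct:.4f} %/yr")
```

```
origin   N= 213  p=0.0020 rate=0.0320 ± 0.0047 %/yr
ring_1   N= 235  p=0.0020 rate=0.0036 ± 0.0018 %/yr
ring_2   N= 362  p=0.0020 rate=0.0093 ± 0.0013 %/yr
ring_3   N= 547  p=0.9142 rate=0.0039 ± 0.0022 %/yr
```

N is the number of site-phase bins, p the global p-value against the
region's Mesolithic null, and the rate the fitted exponential growth in
%/yr with its bootstrap standard error. Classifying the outcomes:

```python
neos = {k: r.neolithization for k, r in results.items()}
print(regime_report({k: r.test for k, r in results.items()}, neos,
                    world.truth, 4_000.0)
      [["region", "true_regime", "pred_regime", "boom_onset"]])
```

```
   region  true_regime  pred_regime  boom_onset
0  origin            1            1         NaN
1  ring_1            2            2      9745.0
2  ring_2            2            2      8148.0
3  ring_3            3            3         NaN
```

All four regions classify correctly: the origin's sustained trend change
(regime 1, 0.032 %/yr against a quasi-stationary forager null), both
travelling-front booms with onsets staggered in ring order (9,745 then
8,148 cal BP), and the dense-forager continuity ring whose record never
leaves its Mesolithic trend (p = 0.91). Across 50 such worlds ≥ 80% of
regions classify correctly (measured in the acceptance suite); residual
errors are mostly marginal false booms just under p = 0.05 — the
near-threshold excursions the method is known to produce under the null,
and the reason excursion lists are read together with the global p-value.

The same pipeline runs from the shell:

```bash
neodem simulate --seed 5 --out sim/
neodem calibrate --dates sim/dates.csv --curve sim/toy_curve.14c --out cal/
neodem front    --dates cal/calibrated.csv --out front/
neodem test     --dates cal/calibrated.csv --curve sim/toy_curve.14c \
                --regions front/regions.geojson --out test/
```

Every command writes a `manifest.json` (full config, seed, input digests)
sufficient to reproduce its outputs byte-for-byte.

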