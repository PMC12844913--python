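# Methods

This note documents the models implemented in `striplight`, the choices made
where the design was genuinely open, and what the synthetic validation can
and cannot show about real field data.

## Geometry of the unit cell

Each intercrop treatment is a periodic cell: two maize rows 0.4 m apart, a
0.6 m gap on either side, and 3–8 soybean rows at 0.3 m spacing, for total
widths 2.2–3.7 m in 0.3 m steps. Only the total widths are reported facts;
the 0.4 m maize spacing and 0.6 m gap are defaults inferred from the
arithmetic of the width series (they reconstruct every printed width
exactly) and are exposed in `LayoutParams`. The cell is split into a maize
strip `Wa = 1.0` m and soybean strip `Wb` at the midline of each gap — the
symmetric choice. Coordinates are one-dimensional across rows, periodic,
increasing east→west, origin on the eastern maize row. With planted density
held at 150 000 plants ha⁻¹ (soybean) and 75 000 ha⁻¹ (maize) regardless of
width, within-row spacing is `n_rows / (density · width)` and widens with the
strip.

## The two-layer strip light-partition model

The maize canopy is split at soybean height `Hb` into an upper layer (maize
alone, leaf area `LAIia = (Ha−Hb)/Ha · LAIa`) and a lower layer shared with
soybean (`LAIiia = Hb/Ha · LAIa`). `LAIa`, `LAIb` are indexed to the *total*
cell ground area; where radiation traverses leaf area concentrated on one
strip, exponents use the strip-local value (`LAI/f`, with `f` the strip's
area fraction). Diffuse radiation moves through the cell via the classic 2-D
black-canopy view factor: a strip of width `W` flanked by opaque walls of
height `H` passes

    vf(H, W) = (√(H² + W²) − H) / W

of isotropic sky radiation (crossed-strings result; 1 for a vanishing wall,
→0 as the wall grows). Four factors are used: beneath the upper layer over
each strip, `vf(Ha−Hb, Wa)` and `vf(Ha−Hb, Wb)`, and beneath the lower layer,
`vf(Hb, Wa)` and `vf(Hb, Wb)`.

Interception is split into nine pathway fractions. Upper layer: `F1`/`F2`
(over the maize strip) and `F3` (sky blocked by the upper walls over the
soybean strip). `Fia` and `Fib` are the fractions of incoming light arriving
beneath the upper layer over each strip. Lower layer: `F4` (direct path into
lower maize), `F5`/`F6` (wall-intercepted light over the maize strip shared
between lower maize and soybean in proportion to `k·LAI`), `F7` (direct path
into the soybean canopy), `F8`/`F9` (wall-intercepted light over the soybean
strip, shared the same way). Maize receives `F1+F2+F3+F4+F5+F9`, soybean
`F6+F7+F8`. A monoculture canopy uses plain Beer's law with `k = 0.34`;
intercrop extinction coefficients default to `ka = 0.43` (maize) and
`kb = 0.64` (soybean), all overridable.

### Literal and consistent variants

The published equation set contains several internal inconsistencies
(mismatched layer subscripts, a leading area factor on the wrong strip, one
competition numerator with mixed coefficients). `variant="literal"`
transcribes it verbatim — useful for transparency — and clamps/flags any
out-of-range value instead of raising. `variant="consistent"` applies the
minimal corrections that restore the symmetry of the competition terms and
the model's own limits:

* every shared-lower-layer term uses the exponent
  `exp(−(ka·LAIiia + kb·LAIb))` and the weight denominator
  `ka·LAIiia + kb·LAIb` (the literal text mixes `LAIa` into some exponents);
* the maize share of shared absorption is weighted `ka·LAIiia` and the
  soybean share `kb·LAIb` in *both* strips (the literal `F9` numerator mixes
  `kb` with the maize leaf area);
* lower-layer wall terms use the lower-layer view-factor complements
  `(1 − vf(Hb, W))`; the literal text reuses the upper-layer complements;
* `F7` and the below-upper-layer flux over the soybean strip `Fib` carry the
  soybean strip's own area fraction `fb` (the literal text uses `Fia`/`fa`);
* `Fia`/`Fib` are clamped to ≤1 with a logged warning if the (heuristic)
  cross-exchange terms overshoot; fractions outside `[0, 1]` raise.

Two printed oddities are deliberately left untouched in *both* variants,
because no reading can be established from the text: `F1` and `F2` differ
only in whether the upper-layer exponent uses strip-local or ground-area
leaf area (both are kept as reported), and the assignment of `F3` and `F9` to
the maize total follows the reported species sums verbatim.

With these corrections the model is exact in the homogeneous limit: for
equal heights, equal `k` and uniform strip-local leaf area,
`Fa + Fb = 1 − e^(−k·LAI_total)` to machine precision (the lower-layer terms
telescope to `fa·(1−e^(−kL)) + fb·(1−e^(−kL))`). The strip-local (`LAI/f`)
exponent reading is adopted over the per-ground-area reading for the same
reason: only it collapses correctly in that limit. An empty canopy yields
zero everywhere, and `Fa + Fb ≤ 1` holds across the seasonal state grid
(property-tested on 1000 random states).

### Validation against the ray tracer, and its verdict

`mc_oracle` is an independent reference: the cross-row plane is a periodic
cell with two turbid, black-leaved boxes (uniform leaf area density
`k·LAI_local/H`), rays enter the top — cosine-weighted for an isotropic sky,
or as a fixed-angle beam — and are walked exactly from box boundary to box
boundary, accumulating per-segment absorption analytically so that
maize + soybean + soil ≡ 1 per ray. The tracer is itself verified against
closed forms: a vertical beam through a homogeneous slab reproduces
`1 − e^(−k·LAI)` to machine precision, an oblique beam matches a fine
z-march, and the diffuse run matches the cosine-weighted slab integral
`1 − ∫cosθ·e^(−τ/cosθ)dθ / ∫cosθdθ` within Monte-Carlo error. Near-grazing
rays (|θ| > 89.9°, flux weight ~10⁻⁶) are clipped to bound the walk length.

The validation grid is the six treatments crossed with the virtual trial's
seasonal canopy trajectory, with ±10 % jitter on heights and leaf areas —
the states the pipeline actually evaluates. On this grid the consistent
variant tracks the tracer closely early in the season but **systematically
overestimates soybean interception at full canopy, by up to ≈ +0.17
absolute** (worst on wide strips with high soybean leaf area; the literal
variant is no better). The `compare` harness and the acceptance script
report the full deviation table. The discrepancy is structural: the
one-dimensional view-factor treatment charges all wall-incident diffuse
light a single fixed optical depth, whereas traced rays take a wide
distribution of path lengths through the canopy walls. Interception
*fractions* from this model should therefore be read as a semi-quantitative
index across treatments, not as radiometric truth — which also cautions
against over-interpreting absolute RUE levels derived from modelled
fractions (relative row/treatment contrasts are much less affected, since
the same bias enters every scope).

## Diurnal PAR simulation

Solar position uses Spencer's Fourier fits for declination and the equation
of time (accuracy a few hundredths of a degree — shadow geometry needs only
±0.5°). The simulator works in local solar time, so solar noon is 12:00
exactly; a clock offset maps timestamps to civil time (the site sits ~0.9°
west of the UTC+8 reference meridian, so solar noon falls ~3.5 min after
clock noon before the equation of time). Timestamps without a declared
UTC offset are refused.

Each 15-min step distributes the day's PAR total along a sine-of-elevation
envelope, split into a direct beam (default 70 %) and isotropic diffuse.
A maize wall of height `Ha − Hb` above the sensor plane casts a cross-row
shadow of reach `(Ha−Hb)/tan(elevation) · |sin(azimuth − row azimuth)|`
toward the anti-solar side; a row receives the beam iff it lies outside every
wall's shadow interval (binary shadows, no penumbra). Diffuse light is
scaled per row by a between-walls sky view, `0.5·(vf(H', d_east) +
vf(H', d_west))`, reusing the black-canopy view factor with the row's
distances to the flanking maize rows. The envelope is normalised after all
sky factors, so an unshadowed point integrates to the daily total within
float precision (asserted to 1 %).

Two sky refinements make the simulator reproduce the field-observed
asymmetries, and both are explicit configuration:

* **Afternoon convective attenuation** (`pm_attenuation`, onset 13:00 solar,
  5 h ramp): warm-temperate monsoon summers are clear in the morning and
  cloud up after midday. Because the western rows lose their beam to maize
  shading only in the afternoon — exactly the dimmed hours — while the
  eastern rows lose the bright morning, this produces the west-over-east
  seasonal PAR surplus. The generator calibrates the depth by bisection so
  the across-treatment west/east ratio on a clear reference day matches the
  configured surplus (+6.5 % by default).
* **Broken-cloud factor**: a seeded multiplicative lognormal factor per
  15-min step (CV 0.30 by default), shared by all rows (the sky is common).

A deterministic clear-sky day cannot show the reported peak-time asymmetry:
the shadow reach vanishes when the sun stands along the rows, so every row
is sunlit in a symmetric window around solar noon and its instantaneous
argmax *is* solar noon. The asymmetry is a statistic of broken cloud: on any
day, a cloud dip at noon relocates the maximum to another bright sample, and
the bright candidates of the eastern border row lie in its sunlit window
(shifted ~after 11:15) while the western row's lie before its afternoon
cut-off (~12:45). The season-mean daily peak therefore falls before noon for
western rows and after noon for eastern rows — the same averaging the
trial's two-year peak times represent. `peak_time` uses a centred moving
mean (default 3 samples, ties to the earlier timestamp) for single-day use;
the season-mean peak statistic (`validation.season_mean_peak_hours`) widens
the window to 7 samples (105 min) so the daily peak reflects the sustained
irradiance window whose edges carry the signal, not a single bright sample.

## Accumulated PAR, intercepted PAR and RUE

Sensor accumulations are kept on two scales: the raw **sum of 15-min
instantaneous readings** (µmol m⁻² s⁻¹ — the trial's "×10⁵" bookkeeping,
used wherever reported numbers are reproduced) and the **physical integral**
(`sum × 900 s / 10⁶`, mol m⁻²). Daily incoming PAR is half the daily total
solar radiation. Intercepted PAR is `Σ_days I_d · F_d` with `F_d` the
consistent-variant soybean fraction for that day's canopy; per-row fractions
split the strip-level `F_d` in proportion to each row's daily sensor sum
(weights normalised to mean 1, so the row mean returns the strip value).
`RUE = ADM / Σ I·F` in g MJ⁻¹; per-plant dry matter converts to an area
basis through the planted density (15 plants m⁻²).

Missing sensor steps: gaps of ≤4 consecutive steps are linearly
interpolated; a day containing a longer gap is dropped and logged; a window
missing more than 10 % of its steps is rejected. Stage windows default to
V5 = 20 Jul (recording start), R3 = 15 Aug, R5 = 10 Sep, R8 = 15 Oct
(harvest), all configurable.

Two RUE estimators are exposed. The *row/stage quotient* `ADM/IPAR` is the
definitional estimator and recovers the generator's ground truth to 10⁻¹⁰
when measurement noise is off. The *treatment-scope trajectory estimator*
regresses cumulative ADM on cumulative IPAR through the origin across the
stage points; it pools the independent destructive samples of all rows and
stages and is the package's default for recovery studies — with three
replicate plants per row at 10 % per-plant noise, row-level quotients carry
~6 % sampling error by arithmetic necessity, while the pooled treatment
estimator recovers truth within 5 % in ≈99 % of seeded replicates.

## Heterogeneity statistics

Row metrics collapse to roles: east = row 1, west = row n, middle = mean of
interior rows; whole-treatment summaries are reported under both the
unweighted role mean and the row-count-weighted mean, labelled. West–east
contrasts use the **ratio of across-treatment means**, truncated toward zero
to one decimal — the only convention that reconciles the trial's printed
row means with its reported percentages (6.589 → 6.5 for whole-period PAR;
5.481 → 5.4 for grain-filling RUE); per-treatment ratios averaged afterwards
do not. The corresponding reported row means ship in `trial_values` as
worked-example inputs.

Duncan's multiple range test pools the one-way error term; a span of `p`
ordered means is tested at the protected level `α_p = 1 − (1−α)^(p−1)`
against the studentized-range quantile (`scipy.stats.studentized_range`,
checked against the classical 5 % table values, e.g. 2.950/3.097/3.190 at
p = 2/3/4, 20 df) scaled by `√(MSE/ñ)` with `ñ` the harmonic mean group
size; a narrower span is declared significant only if every enclosing span
is. Letters are assembled by the standard sweep over descending means, so
groups between two groups sharing a letter share it too. Linear fits are
ordinary least squares (`scipy.stats.linregress`); a constant response
returns slope 0 and r² 0, a constant predictor is an error.

## The virtual experiment

The generator emulates the trial's data streams with known ground truth:

* **Weather**: seasonal clear-sky sinusoid (21 + 8·cos term, MJ m⁻² day⁻¹)
  times a seeded lognormal day factor capped at clear sky.
* **Canopy growth**: logistic curves — maize to 2.6 m and strip-local LAI
  5.5, soybean to 0.8 m and strip-local LAI 2.75, wider strips carrying
  slightly more soybean leaf area (+4 % per row beyond five). Plausible for
  the cultivars and climate; configuration, not measured fact.
* **Sensors**: `simulate_day` per day with the calibrated afternoon
  attenuation and seeded broken cloud, then multiplicative lognormal reading
  noise (CV 5 %).
* **Traits**: per-row dry matter truth is `RUE_row × cumulative IPAR_row`,
  with `RUE_row` set by role (east 1.37, middle 1.50, west 1.44 g MJ⁻¹ —
  within the reported grain-filling range) times a distance-from-maize
  gradient (+8 % per metre, recorded per row in the ground truth). Three
  replicate plants per row and stage with 10 % lognormal noise; leaf area
  follows dry matter through a stage-specific area:mass ratio
  (140/95/70/45 cm² g⁻¹ at V5/R3/R5/R8).
* **Yield**: harvest index 0.45 on maturity dry matter, decomposed into
  grains (100-seed weight 18 g) and pods (2.2 grains per pod); per-area
  yield via planted density.

Regeneration under one seed is byte-identical (seeded generator streams are
spawned from a single `SeedSequence`; exports round floats to fixed
precision); the fixture manifest hashes the seed, configuration and files.

What passing tests on this generator do **not** show: the generator shares
the interception model with the pipeline (its dry-matter truth is built from
the same `Fb`), so parameter recovery demonstrates pipeline correctness and
statistical power, not the radiometric accuracy of the interception model —
that question is delegated to the ray-tracing comparison, which quantifies
the model's bias. Real sensor data also carry autocorrelated cloud fields,
drift and fouling that the lognormal noise does not emulate, and real trait
gradients need not be log-normal around a smooth distance trend.

## Numerical choices and problem sizes

Fractions are accepted within `[−10⁻⁹, 1+10⁻⁹]` and clipped into `[0, 1]`;
view factors short-circuit to 1 at zero wall height; shared-layer weights
define 0/0 as 0 (empty lower layer); `peak_time` breaks ties toward the
earlier timestamp; the tracer nudges rays 10⁻⁹ m off exact box boundaries.
Validation studies default to: 50-state seasonal grids at 10⁵ rays per state
(Monte-Carlo standard error ≈ 0.002 on a fraction), 100 replicate 10-day
experiments for recovery, and full-season (88-day) runs for peak and surplus
statistics — sizes chosen so the whole suite replays in well under a minute
on one core while keeping Monte-Carlo error far below the effects measured.

## Known limitations

* No leaf scattering, reflectance, spectral (red:far-red) or sun/shade leaf
  physiology anywhere in the radiation chain; leaves are black absorbers.
* The analytic partition is one-dimensional and diffuse-effective; its
  soybean fraction is biased high at full canopy (quantified above), and no
  hourly sun-angle dependence enters the daily fractions.
* Binary shadows at sensor height; no penumbra; maize strips are treated as
  walls at the two row lines.
* The afternoon-attenuation calibration targets the across-treatment surplus
  on one clear reference day; cloudy-season realisations scatter around the
  target (typically within ±0.5 percentage points).
* Maize growth and LAI trajectories are assumptions recorded in the fixture
  manifest, not reported values; maize-side RUE and yield are out of scope.
* Plot-scale replication blocks, plot length and edge-exclusion bookkeeping
  are not modelled; replicate structure enters only as three plants per row.
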