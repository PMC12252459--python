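# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline, and what the synthetic-data generator does and
does not emulate.

## Thermography

A thermal scene is a 2-D surface-temperature raster (°C) with a boolean
plant mask. **Plant temperature (PT)** is the arithmetic mean of the raster
over the mask. The field convention does not pin down an aggregator (mean,
median or mode of the contoured region); the mean matches the default
region statistic of thermal-camera analysis software and is the contract
here, with min/max/median exposed as secondary outputs
(`region_statistics`). **Soil temperature (ST)** is the mean over the mask
complement by default; an explicit soil sub-mask can exclude rock or sky
pixels. **Thermal decoupling** is TD = PT − AT in kelvin; negative values
mean the plant is cooler than the air at plant height. TD in K and °C are
the same difference unit.

**VPD** uses the Tetens saturation vapor pressure
e_s(T) = 0.6108 · exp(17.27 T / (T + 237.3)) kPa — the standard
agrometeorological constants — and VPD = e_s(AT)(1 − RH/100). Valid for
RH ∈ [0, 100] %.

## Architecture indices

**Porosity** PI = 1 − (plant pixels)/(tight axis-aligned bounding box of
all plant components). PI is bounding-box-orientation dependent by
contract (it mimics the height × width of a cropped top-down photograph);
rotating the mask changes PI, which is documented rather than corrected.

**Circularity** CI = 4πA/P². Polygon input uses the exact shoelace area
and edge-length perimeter. Raster input counts pixels for A and estimates
the geometric perimeter with the Crofton formula (4 directions): naive
boundary-step counting overestimates P by ~5 % on a disk and would deflate
CI to ~0.90, whereas the Crofton estimator is within 0.1 % on a
100-px-radius disk and within 0.3 % of the elliptic-integral value on a
2:1 ellipse at 512 px. Residual discretization bias shrinks with
resolution; the raster/polygon discrepancy is documented, not resolved.
Plant height is always user-supplied (tape-measured), never inferred from
imagery.

## Heat resistance

Photoinactivation PhI = (1 − FhT/Fmax) × 100, with FhT the Fv/Fm after
heating to T and Fmax the unheated control. Raw PhI is kept (it can be
negative when a heated leaf out-fluoresces the control, or exceed 100);
clipping to [0, 100] is report-side only, and negative PhI counts as
"below 50 %" for bracketing.

**LT50** is the bracketing linear interpolation between the highest
treatment with PhI < 50 % (T_lo) and the lowest with PhI > 50 % (T_hi):
LT50 = T_lo + (50 − PhI_lo)(T_hi − T_lo)/(PhI_hi − PhI_lo). Tie rule:
PhI exactly 50 at a node returns that node (measure-zero event, avoids
bracket ambiguity). Non-monotone PhI sequences (possible with measurement
noise) use the first upward 50 % crossing in temperature order and carry a
`non_monotone` flag. Curves never exceeding 50 % are right-censored at the
hottest treatment; curves above 50 % at the mildest treatment are
left-censored. Censored individuals are excluded from species means and
counted separately. On a noise-free logistic with slope s ≥ 3 °C and the
standard 25/35/45/55/60 °C grid, the chord bias of the interpolation is
below 0.7 °C for LT50 ∈ [38, 52] (exactly the analytic chord crossing —
the tests verify both identities). Parametric sigmoid fitting is
deliberately not the primary estimator.

Several leaves per individual measured at the same treatment temperature
are averaged per individual before bracketing; per-leaf interpolation is
an alternative a caller can implement by passing one curve per leaf.

## Statistical engine

* **PCA** of the five drivers always uses the correlation matrix
  (standardized variables) because the units are mixed (°C, %, km h⁻¹,
  µmol m⁻² s⁻¹). Components are ordered by decreasing variance; each
  component's sign is fixed so its largest-|loading| variable loads
  positively.
* **Additive smooth model.** Gaussian, identity link. Each predictor
  enters as a cubic B-spline smooth (basis dimension k = 10 by default,
  the usual basis-size default checked by k-index diagnostics) with an
  integrated-squared-second-derivative penalty. Because the model is
  Gaussian the penalized least-squares problem is solved in closed form
  (no IRLS), and the penalty weights are selected by minimizing GCV on the
  log-penalty scale with Nelder-Mead; a tiny additive term in the GCV
  numerator breaks ties between exact fits in favor of the smoother one,
  which makes the degenerate noise-free case well-defined (the penalty
  null space is the linear trend, so noise-free linear signals shrink to
  edf = 1 per smooth). Per-smooth effective degrees of freedom are the
  per-coefficient hat-trace contributions; significance uses the Wald
  statistic of the smooth's coefficients with the sandwich covariance
  truncated at rank ≈ edf, referred to F(edf, n − total edf) — the usual
  approximation for penalized fits, slightly liberal (measured type-I
  ≈ 0.10–0.12 at α = 0.05 in the test suite's null simulations).
* **Sequential (Type-I) variance partition.** The TD trait model is
  decomposed in the declared term order (PH, CI, PI, PH:CI, date); each
  term's SS is the RSS drop when added after its predecessors, so term SS
  plus residual SS reconstruct the total SS exactly and
  explained-% = SS/total SS. The partition is order-dependent whenever
  predictors correlate — that is a property of the decomposition, asserted
  in the tests, not a bug. `anova_table_from_ss` replays the same
  arithmetic from published SS columns. A numerically-zero total SS
  (constant response) reports 0 % everywhere.
* **Classical tests** wrap scipy/statsmodels: paired t on PT − AT;
  Mann–Whitney U with exact p for min(n) ≤ 8 without ties, otherwise the
  tie-corrected normal approximation with continuity correction; one-way
  ANOVA with (k−1, N−k) df (zero within-group variance raises — F is
  undefined); Spearman ρ with average ranks for ties. Two-sided p-values,
  α = 0.05, no multiple-testing correction anywhere.
* **Diagnostics**: Shapiro–Wilk (3 ≤ n ≤ 5000) and the studentized
  Breusch–Pagan test, with pass/fail flags at α = 0.05.

## Synthetic data

The generators define the study conditions; their defaults are fixed once
and are not tuning knobs.

* **Microclimate.** Gaussian copula with Gaussian margins over
  (AT, ST, RH, WS, PAR). Five pairwise correlations are published
  (AT–ST 0.68, PAR–AT 0.64, PAR–RH −0.64, WS–AT −0.25, WS–RH −0.22) and
  are matched directly; the five unpublished cells are filled with
  physically plausible PSD-consistent values (AT–RH −0.60, ST–RH −0.55,
  ST–PAR 0.60, ST–WS −0.10, WS–PAR −0.10), so the leading-axis variance
  split that emerges (~57 %/23 %) is indicative, not an exact target.
  Margins: AT 19.3 ± 4.9 °C and RH 37 ± 13.5 % (published); ST 24 ± 7 °C,
  WS 5 ± 3 km h⁻¹, PAR 1100 ± 450 µmol m⁻² s⁻¹ (realistic clear-day
  alpine values). Margins are not truncated at physical bounds — a
  truncation would distort the target correlations; range enforcement is
  the validator's job on real data. Indefinite user-supplied matrices are
  repaired by eigenvalue clipping and rejected if the repair moves any
  cell by more than 0.1.
* **Plant temperature.** PT = f(PC1) + ε with the monotone cubic
  f(x) = 12.6 + 2.0x + 0.25x³ (strictly increasing; the intercept places
  mean PT ≈ 6.7 K below mean AT, the magnitude of daytime decoupling the
  generator emulates). ε ~ N(0, 3.7²): the noise SD was calibrated once by
  simulation so that the refitted additive model's adjusted R² averages
  0.80 at n = 108 (0.797 ± 0.04 over replicates), the explanatory power
  the model is meant to exhibit.
* **TD trait dataset.** Six species (3 rosettes, 3 dwarf shrubs,
  27 individuals, heights 4–40 cm, paired sampling dates at day offsets
  0/1/36) with per-individual trait jitter (6 % relative SD). TD is linear
  in traits: intercept 3.9, β_PH −0.005, β_CI −9.5, β_date −0.11 per day,
  noise SD 1.8 K. Sampling date enters as a numeric covariate (days),
  matching the single numerator df of the published table. The
  coefficients were calibrated once so the mean sequential shares land
  near the published partition (height ~24 %, circularity ~19 %,
  date ~25 %); because height and circularity are correlated across
  species, the *marginal* height effect (≈ +0.06 K cm⁻¹, taller plants
  less decoupled) is carried almost entirely through the circularity
  pathway — shorter, rounder plants are the more strongly decoupled, as
  intended. Single 27-plant campaigns scatter by ±8–10 percentage points
  around these means; only ensemble means are meaningful targets.
* **Heat assay.** Fv/Fm(T) = Fmax·logistic((LT50 − T)/s) with s = 3 °C,
  Fmax = 0.8, sampled at 25/35/45/55/60 °C; PhI is exactly 50 % at
  T = LT50. Noise is truncated Gaussian (resampled into [0, 1], because
  fluorescence ratios are bounded; hard clipping would bias the upper
  plateau). The default cohort is 6 species × 7 individuals with species
  means 35.2–54.2 °C (±1.5 °C between individuals), spanning the
  published range. True LT50 values are retained on each curve for
  recovery tests.
* **Canopy masks.** Disk, ellipse, annulus and multi-lobe rasters with
  closed-form CI/PI for the first three (ellipse perimeter via the
  complete elliptic integral; annulus CI = (R−r)/(R+r)); multi-lobe shapes
  have no closed form and serve as "CI below the disk bound" fixtures.

**What passing tests do not show.** The generator reproduces the
*statistical* structure of the field data — correlations, smooth response,
linear trait effects, logistic damage — not its physics. There is no leaf
energy balance, no stomatal behavior, no spatial or temporal
autocorrelation, no heteroscedasticity across species, and trait–TD
relations are linear by construction. Passing the recovery tests shows
the estimators are correct, not that the field effects are of these
magnitudes; the headline field values (mean TD, species LT50, ρ between
TD and LT50) can only be reproduced exactly from the original deposited
tables, which the pipeline accepts through the same CSV interfaces
("replay" path).

## Pipeline and reproducibility

One top-level seed spawns independent per-stage substreams
(`numpy.random.SeedSequence.spawn`), so disabling a stage never changes
another stage's draws. Every run writes a manifest with the seed, package
version, per-stage child seeds and SHA-256 of each output CSV; re-running
with the same config reproduces the files byte-for-byte. Problem sizes
used throughout (n = 108 observation campaigns, 27-plant trait datasets,
42-individual assay cohorts, 10 000-row copula fidelity draws, 20–50
replicate ensembles) mirror the study design at the scale where the
ensemble statistics stabilize.
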