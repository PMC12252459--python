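# alpinetherm

Analysis pipeline for **thermal decoupling and heat resistance in alpine
plants**: from infrared thermal rasters, top-down canopy masks and
chlorophyll-fluorescence heat assays to the statistical models that relate
them.

## The scientific problem

Short, compact alpine plants are classically described as "heat traps":
their canopy temperature decouples from the surrounding air
(TD = PT − AT, plant minus air temperature) and is often warmer. But under
Mediterranean-type alpine summers the opposite can hold — plants can run
several kelvin *cooler* than the air — and that decoupling interacts with
how much heat the leaves can actually survive. The pipeline quantifies
four linked questions:

1. **Which microclimate drivers set plant temperature?** Air temperature
   (AT), soil temperature (ST), relative humidity (RH), wind speed (WS) and
   photosynthetically active radiation (PAR) are strongly collinear, so
   they are reduced by correlation-matrix PCA and the leading components
   enter a penalized additive (smooth) model of plant temperature:
   PT = β₀ + f₁(PC1) + f₂(PC2) + ε.
2. **How strongly is the plant decoupled?** TD per plant and period, tested
   with paired *t* (or Mann–Whitney U) of PT against AT.
3. **Which architectural traits explain TD?** A linear model
   TD ~ PH + CI + PI + PH:CI + date, decomposed by sequential (Type-I) sums
   of squares with an explained-variance column (term SS / total SS).
   Plant height PH (cm), circularity index CI = 4πA/P², and porosity index
   PI = 1 − A/(bounding box) come from canopy masks or polygons.
4. **Does decoupling relate to heat resistance?** Leaf damage after heating
   to 25/35/45/55/60 °C is measured as photoinactivation
   PhI = (1 − FhT/Fmax) × 100 from dark-adapted Fv/Fm, and LT50 is the
   temperature where PhI crosses 50 %, found by bracketing linear
   interpolation (with right/left censoring when the curve never crosses).
   Species LT50 is compared across growth forms and rank-correlated
   (Spearman ρ) with TD.

A synthetic-data generator reproduces the statistical structure of every
input (Gaussian-copula microclimate with the published driver correlations,
smooth PT response, linear-in-traits TD, logistic Fv/Fm decline with known
LT50, parametric canopy shapes with closed-form CI/PI), so the entire
pipeline is testable without the original field data.

## Worked example

```python
from alpinetherm.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=1, outdir="alpinetherm_run"))
print(f"additive model adjusted R2 = {res['smooth_fit'].adjusted_r2:.3f}")
print(res["td_anova"].round(2))
print(res["lt50_by_species"][["species", "mean_lt50", "n"]].round(1))
```

prints (seed 1):

```
additive model adjusted R2 = 0.717
           numDF  denDF  Sum Sq  Mean Sq      F     p  explained_%
term
PH             1   21.0   91.02    91.02  18.73  0.00        30.72
CI             1   21.0   32.79    32.79   6.75  0.02        11.07
PI             1   21.0    3.38     3.38   0.69  0.41         1.14
PH:CI          1   21.0    3.33     3.33   0.69  0.42         1.12
date           1   21.0   63.71    63.71  13.11  0.00        21.50
Residuals     21    NaN  102.06     4.86    NaN   NaN        34.45
                  species  mean_lt50  n
0      Azorella prolifera       42.0  7
1   Berberis empetrifolia       53.6  7
2  Hypochaeris tenuifolia       47.3  7
3        Phacelia secunda       48.2  7
4    Senecio pachyphyllos       34.6  7
5            Viola aizoon       47.8  7
```

Reading the output: the smooth model recovers most of the plant-temperature
variance from the leading microclimate axis; the sequential partition
attributes TD variance to height, circularity and sampling date (one random
27-plant campaign, so single-seed shares scatter around their generating
values); and per-species LT50 means from the interpolated assay curves span
the rosette/dwarf-shrub range, with *Senecio pachyphyllos* least and
*Berberis empetrifolia* most heat-resistant.

The same stages are available from the shell:

```sh
alpinetherm simulate --seed 1 --outdir run     # synthetic input tables
alpinetherm lt50 --assay run/assay.csv         # LT50 per individual
alpinetherm stats --td-dataset run/td_dataset.csv
alpinetherm run-all --seed 1 --outdir run      # everything + manifest
```

All tabular I/O is CSV. Observation tables use columns
`individual, species, growth_form, date, period, PT, ST, AT, RH, WS, PAR,
TD, VPD`; assay tables use
`individual, species, treatment_temp_C, fvfm, is_control`; trait tables use
`individual, species, PH, CI, PI`. Thermal rasters and masks are read from
plain CSV grids or PGM images.

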