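# lumpanel

**Land-use-mix exposure in sausage network buffers, and within/between
panel models of walking and cycling.**

`lumpanel` is for epidemiologists and geographers who study how the
residential built environment relates to physical activity in
longitudinal cohorts. It implements the full chain from GIS inputs to
pooled model estimates:

1. **Sausage network buffers** — the part of the pedestrian/cyclist
   road network within network distance *d* ∈ {500, 1000, 1600} m of a
   residence (edges cut at the exact distance-*d* point), dilated by a
   25-m corridor. Roads closed to pedestrians and cyclists (highways)
   are excluded up front.
2. **Land-use mix (LUM)** — the normalized entropy of land-use class
   area shares inside each buffer,

   `LUM = -[Σⱼ pⱼ ln pⱼ] / ln N`,

   with *N* = 11 the scheme size (not the classes present) and the
   convention 0·ln 0 = 0; 0 = single use, 1 = perfect mix. Each survey
   wave is linked to the land-use snapshot of an earlier year, so
   exposure precedes outcome. Models use `10 × LUM`, i.e. effects per
   10-percentage-point change in mix.
3. **Harmonization** — two questionnaire instruments (days × minutes
   per day; sessions × minutes per session over two weeks) reduced to
   average minutes/week of walking and cycling; cohorts pooled;
   analysis restricted to persons observed in all waves at one
   residence; covariates completed by chained-equations multiple
   imputation.
4. **REWB model** — the random-effects within-between (hybrid/Mundlak)
   model

   `PA_it = β₀ + β₁W(x_it − x̄ᵢ) + β₂B x̄ᵢ + β₃Zᵢ + β₄γ_it + vᵢ + ε_it`,

   fit by REML with a person random intercept: β₁W is the *within*
   effect (a person's own exposure changing over time) and β₂B the
   *between* effect (differences in average exposure across persons).
   Results are combined across imputations with Rubin's rules.

A synthetic world with known ground truth (grid road network, evolving
11-class parcel mosaic, 3-wave panel generated from the model equation)
makes the whole chain runnable and testable with no external data.

## Worked example

Run the pipeline end-to-end on a synthetic world (60 persons per
cohort, 20% movers, 5 imputations):

```python
from lumpanel.pipeline import RunConfig, run_pipeline
from lumpanel.synthetic import WorldConfig, generate_world

cfg = RunConfig(seed=11, out_dir="example_out", n_imputations=5)
world = generate_world(WorldConfig(seed=11, n_persons=60))
bundle = run_pipeline(cfg, world=world)
print(bundle["results"][["outcome", "buffer_size", "effect_type",
                         "beta", "ci_low", "ci_high", "p"]].round(2))
```

which prints (one row per outcome × buffer size × effect type):

```
     outcome  buffer_size effect_type    beta  ci_low  ci_high    p
 walk_min_wk        500.0      within  -25.85 -109.32    57.63 0.54
 walk_min_wk        500.0     between   -8.92  -33.65    15.81 0.48
 walk_min_wk       1000.0      within -145.64 -360.64    69.35 0.18
 walk_min_wk       1000.0     between  -11.48  -56.90    33.94 0.62
 walk_min_wk       1600.0      within -133.13 -503.48   237.22 0.48
 walk_min_wk       1600.0     between   57.90   -6.98   122.79 0.08
cycle_min_wk        500.0      within  -16.49 -112.11    79.14 0.74
cycle_min_wk        500.0     between    8.97  -12.37    30.30 0.41
cycle_min_wk       1000.0      within -120.93 -367.00   125.15 0.34
cycle_min_wk       1000.0     between    5.04  -34.21    44.29 0.80
cycle_min_wk       1600.0      within   98.91 -323.18   520.99 0.65
cycle_min_wk       1600.0     between   -2.68  -59.55    54.18 0.93
```

`beta` is in minutes/week per 10-percentage-point change in LUM: e.g.
the walking/1600-m *between* row estimates that persons whose average
mix is 10 points higher walk 58 more minutes per week (95% CI −7 to
123 — at 96 analysis persons the intervals are wide; the bundled
recovery simulations at 2000 persons pin the generator's true
β₁W = −5, β₂B = +10 to within Monte Carlo error). The manifest records
the sample flow, e.g.

```
persons_in 120 = excluded_movers 24 + persons_kept 96
```

The same run is available from the shell:

```bash
lumpanel simulate --seed 11 --out-dir world/   # write the synthetic world
lumpanel run --seed 11 --out-dir example_out   # end-to-end pipeline
```

Outputs: `exposures.csv` (person-wave LUM per buffer size),
`results.csv` (the tidy effects table), `manifest.json` (seeds,
versions, exclusion counts), `ground_truth.json` (synthetic runs only).

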