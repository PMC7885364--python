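# Methods

`lumpanel` implements an exposure-to-inference chain for studying how
land-use mix (LUM) in the residential environment relates to weekly
walking and cycling time in longitudinal cohort data: sausage network
buffers around residences, entropy-based LUM inside those buffers with
exposure preceding outcome, harmonization of two questionnaire
instruments to minutes/week, pooling of two cohorts restricted to
non-movers, chained-equations multiple imputation of covariates, and a
random-effects within-between (REWB) linear mixed model combined across
imputations with Rubin's rules. A fully synthetic world with known
ground truth stands in for the access-restricted cohort and national GIS
data, so every stage is testable offline.

## Sausage network buffers

A sausage (line-based) buffer represents the area actually reachable
from home on foot or by bicycle. Construction:

1. **Accessible graph.** Road polylines are loaded into an undirected
   multigraph; segments closed to pedestrians and cyclists (e.g.
   highways) are dropped *before* graph construction, so they can never
   contribute reachable area. Endpoints within 0.01 m are merged — pure
   topology repair for vector data; the tolerance is far below any
   real inter-road spacing, so distinct roads are never bridged.
2. **Snapping.** The residence is projected to the nearest point of the
   nearest edge. The maximum snap distance defaults to 100 m;
   residences farther from the network are reported and excluded, the
   same way ungeocodable addresses are excluded from cohort analyses.
   Distance ties are broken by lowest segment id for determinism.
3. **Network extract.** Single-source shortest paths (Dijkstra, edge
   length as the only cost) from the snapped origin, inserted as a
   virtual node splitting its host edge. Edges are *cut at the exact
   network distance d* by linear interpolation along the polyline,
   rather than selected whole: whole-edge selection overstates reach,
   and "within distance d" is a statement about network distance to a
   point. The origin's host edge is walked bidirectionally from the
   snap offset.
4. **Dilation.** The reachable polylines are unioned and buffered by
   the corridor half-width w = 25 m with round caps and joins
   (16 segments per quadrant; the polygonal circle approximation is
   within 0.16% of the true area even for a bare disk, and far closer
   for sausage shapes whose boundary is mostly straight). Union before
   area measurement guarantees overlapping corridors are counted once.

Buffer distances default to 500, 1000 and 1600 m, with 1000 m the main
exposure. Degenerate cases (d = 0, or an origin on an isolated scrap of
network) produce a flagged w-radius disk instead of an undefined
exposure; downstream stages may exclude flagged rows.

Invariants enforced by tests: buffers are monotone in d; contained in
the Euclidean disk of radius d + w + snap distance; unaffected by
inaccessible edges; and their areas agree with an independent 0.5-m
rasterization oracle within 0.5% and with the closed form
4dw + pi w^2 for an isolated straight road.

## Land-use mix entropy

Within each buffer, class areas a_j are the polygon-intersection areas
with the land-use mosaic of the exposure year, and

    LUM = -[ sum_j p_j ln p_j ] / ln N ,   p_j = a_j / sum_k a_k ,

with the convention 0 ln 0 = 0. **N is the scheme size (11), not the
number of classes present in the buffer** — a buffer containing two of
eleven classes in equal shares scores ln 2 / ln 11 ≈ 0.289, not 1. This
keeps scores comparable across buffers and waves. LUM is 0 for single
use, 1 for a perfectly even mix. The 11-class scheme itself is
configurable (the original national classification is study-specific);
the shipped labels are generic.

The mosaic is assumed wall-to-wall. Gaps are data defects: uncovered
buffer area is excluded from the denominator rather than treated as a
12th class, with a warning once the gap exceeds 5% of the buffer.
Invalid polygons are repaired (`make_valid`) and logged.

In the models the exposure enters as `lum_scaled = 10 × LUM`, so
coefficients read as minutes/week per 10-percentage-point change in LUM.

**Chronology.** Each survey wave is linked to the land-use snapshot of a
configured *earlier* year (exposure precedes outcome); a mapping that
points to a later year is a configuration error.

## Outcome harmonization

Both instruments are reduced to average minutes/week of walking and of
cycling:

* **Days × minutes/day instrument (SQUASH-type).** Complete items
  multiply out. A duration without days counts as one active day per
  week. Days without a duration get the median minutes/day of complete
  responders substituted; the median is computed per wave and activity
  (the least surprising stratification; configurable to unstratified).
* **Two-week recall instrument (LAPAQ-type).** sessions ×
  minutes/session / 2.

Sex and education are treated as time-invariant and fixed at their
baseline values; age, marital status, income (common 4-level coding),
and employment vary by wave. The analysis sample keeps only persons
observed in *all* waves whose residence moved less than 1 m (geocoding
jitter) across waves; exclusion counts are reported per rule so the
sample flow always balances.

Covariate missingness is handled by chained equations (predictive mean
matching) over the covariates plus auxiliaries (self-rated health,
smoking, BMI), producing m = 5 completed datasets by default from a
fixed seed. PMM draws imputed values from observed donors, so
categorical codes remain valid without explicit categorical models.
Outcomes and exposures are never imputed. Imputation runs per cohort
before pooling; cohorts are then concatenated with the cohort label
retained as a model covariate.

## The REWB model

For person i at wave t,

    PA_it = b0 + b1W (x_it - xbar_i) + b2B xbar_i + b3 Z_i + b4 g_it
            + v_i + eps_it ,

where x_it is `lum_scaled`, xbar_i its mean over the person's observed
waves, Z_i time-invariant covariates, g_it time-varying covariates,
v_i ~ N(0, var_v) a person random intercept and eps_it ~ N(0, var_eps)
the residual. b1W is the *within* effect (change in outcome when a
person's own exposure deviates from their mean) and b2B the *between*
effect (outcome difference per unit difference in average exposure
across persons). On balanced data without extra covariates b1W equals
the fixed-effects (within) estimator and b2B the between-means OLS
slope — the "best of both worlds" property; both equalities are tested
to 1e-6.

Estimation is REML (configurable to ML) via a standard linear
mixed-model fit; inference is Wald with normal-approximation 95%
intervals. Estimates across imputations are combined with Rubin's
rules (pooled estimate = mean; total variance = mean within-imputation
variance + (1 + 1/m) × between-imputation variance); Barnard–Rubin
small-sample degrees of freedom are available behind a flag, normal by
default. No wave fixed effect is included by default (age absorbs the
secular trend); a wave indicator can be added through the covariate
list. Boundary fits (var_v estimated at 0) are flagged, not silently
refit. A zero within-person exposure variance makes b1W inestimable
and is a hard error; rank-deficient designs are rejected with the
aliased terms listed.

`run_all_models` fits both outcomes × all buffer sizes, pools across
imputations, and emits one tidy row per (outcome, buffer size, effect
type); failed cells are marked and the run continues.

## Synthetic world

The generator emulates the *structure* of the real setting, not its
morphology: a square lattice road network (6.4 km side, 100-m spacing,
5% of edges inaccessible), a wall-to-wall mosaic of 150-m square
parcels over 11 classes, residences placed 5–40 m off accessible edges
inside a margin that keeps the largest buffer within the mosaic, and a
3-wave panel (fieldwork 2004/2008/2012, exposure snapshots
2003/2007/2011).

Calibration targets come from the descriptive statistics of the study
population this emulates: the class-probability preset (dominant class
0.83) yields a mean 1000-m-buffer entropy of ~0.30 (SD ~0.05), and the
per-parcel change probability (0.028 per wave transition, with 62% of
changes drifting toward the dominant class so decreases outweigh
increases) yields ~44% of person-observations with an entropy change
from the previous wave. These presets were tuned once against those
two statistics and then frozen. The per-transition change magnitudes in
the geometric world are smaller than the analytic generator's (whose
decrease/increase means are -0.05/+0.03 on the entropy scale); only the
mean level and change frequency are calibration targets.

Outcomes follow the REWB equation exactly with defaults b0 = 300,
b1W = -5, b2B = +10, var_v = 2500, var_eps = 10000 (minutes/week scale),
plus modest covariate effects; negative draws are floored at zero with
the truncated fraction logged. The intercept is set high enough that
truncation stays below 1% of draws, keeping the linear fitting model
well specified for recovery checks. Covariate missingness is MCAR at
2–8% per variable by default, mirroring the observed missingness range.
Movers (20% of persons) receive a second residence from wave 2 or 3.

Two scales are shipped: the geospatial world defaults to 100 persons
per cohort (the geometry stage dominates run time), while the
analytic-exposure generator — which draws exposure trajectories from
the calibrated statistics directly, skipping geometry — defaults to
1000 persons per cohort (2000 total × 3 waves) and backs the
parameter-recovery simulations. Recovery runs disable covariate
missingness so they measure the estimator, not imputation noise; the
imputation stage is validated separately on MCAR data with known
marginals.

What the generator does *not* emulate: realistic street morphology,
spatial autocorrelation of land-use change, residential self-selection
(movers are flags, not behavior), zero-inflation of activity minutes,
and measurement error in self-reports. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the stated
model, not robustness to those real-data features.

## Numerical choices

* Node merge tolerance 0.01 m; snap tolerance 100 m; non-mover
  residence tolerance 1 m.
* Buffer quadrant segments 16; raster oracle cell 0.5 m.
* Entropy clamps roundoff to [0, 1]; share sums are validated to 1e-9.
* Deviations from person means are exact (groupby-transform); the
  decomposition identity (deviations sum to 0 per person) is tested.
* Mixed-model fits retry with Powell on linear-algebra failures of the
  default optimizer; non-convergence is surfaced in the results table.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; reruns are byte-identical.

## Known limitations

* Vector IO is GeoJSON-only, with a declared-CRS string and a
  degree-envelope heuristic in place of full CRS machinery; inputs must
  already be in a projected meter CRS (e.g. EPSG:28992).
* The imputation chain imputes coded categoricals via PMM rather than
  fully categorical conditional models.
* p-values are Wald/normal; no likelihood-ratio or Kenward–Roger
  options.
* The pipeline models each buffer size separately; no joint inference
  across sizes.
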