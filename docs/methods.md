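# Methods

`aggsdm` implements a species *aggregation* distribution model: rather
than modelling abundance, it models the occurrence of unusually large
counts — aggregations, defined per species as gridded counts at or above
the empirical 90th percentile of that species' positive counts — and
evaluates the resulting interannual aggregation indices against
independently observed ocean fields. This note records the model, its
assumptions, the tunable parameters, and the choices made where the
design was genuinely open.

## Observation processing

Raw observations are 3-km transect-bin records carrying a behavior code
(flying / on water / feeding). Flying birds are removed — only birds
sitting on the water or feeding are treated as evidence of foraging
aggregation behavior — and the retained counts are summed onto a regular
0.1° grid per cell and day. Survey effort (cell-day visits with a
coverage fraction, the surveyed area divided by cell area) supplies true
absences: a surveyed cell-day with no sighting of a species enters as a
zero count. Cell membership uses half-open intervals `[edge, edge+res)`,
so a point exactly on an upper edge belongs to the next cell.

Two quality filters are applied: cells with coverage fraction strictly
below 5% are removed, and survey years with fewer than 50 raw 3-km
records are removed entirely. Both bounds are strict `<`, so exactly-5%
coverage and exactly-50-record years are retained.

The aggregation cutoff is the empirical 90th percentile of a species'
positive counts, by linear interpolation of order statistics at rank
h = (n−1)·0.9 (the common default in mainstream numerical stacks).
Labels are `presence = (count > 0)` and `aggregation = (count ≥ cutoff)`;
the tie rule `≥` guarantees the maximum count is always an aggregation
and that aggregation implies presence. At least 10 positive counts are
required to define a cutoff. A sensitivity routine recomputes cutoffs
over quantiles 0.85–0.95 and reports the fraction of labels that flip.
Whether labeling should operate on 3-km-bin or grid-cell counts is
ambiguous in principle; the package labels gridded cell-day counts,
matching the scale at which predictors are attached.

## Predictors

Eleven covariates are matched to each labeled cell-day: SST (°C), SSH
(m), chlorophyll a (mg/m³), wind-stress curl (N/m³, centered differences
with the stencil half-width of a 0.5° window, zonal spacing scaled by
cos latitude, stencil clipped one-sided at domain edges), total kinetic
energy ½(u²+v²) (m²/s²; the standard kinetic-energy-per-unit-mass form),
the 0.3°-window standard deviations of SST and SSH (rolling centered
window; a block mode would also be defensible but the rolling form keeps
the field on the full grid), depth (positive magnitude, m), rugosity
(0.3° SD of depth), and great-circle distances (km, sphere radius
6371.0088 km) to the breeding colony (Southeast Farallon Island,
37.698° N 123.003° W, configurable) and to shore (the eastern grid edge
in synthetic runs). Neighborhood statistics use the available sub-window
at edges; NaN cells propagate as NaN and rows with any missing covariate
are dropped and counted.

## Hurdle model

Aggregation probability factorizes as

    Pr(Agg) = Pr(1) × Pr(Agg | 1)

where stage one (presence/absence) is fit on all records and stage two
(aggregation/non-aggregation) only on presence records. Both stages are
ensembles of gradient-boosted classification trees with bernoulli loss,
interaction depth 3, bag fraction 0.6, and learning rates 0.01
(presence) and 0.005 (aggregation). Each of the 50 members trains on an
independent stratified 75/25 split and records held-out AUC (rank-based,
ties half-credit) and TSS (max over thresholds of sensitivity +
specificity − 1). "50 iterations of fourfold cross-validation" is read
as 50 independent random 75/25 splits yielding 50 models whose mean is
reported; the alternative full-4×-fold reading (200 fits) would change
only the amount of averaging. Members cap at 2000 trees and stop early
when internal validation deviance has not improved for 10 rounds — tree
counts are otherwise unidentified, and stagewise early stopping is
standard practice. No class reweighting is applied.

Prediction averages member probabilities per stage *before* multiplying
the stages, cell by cell on the daily covariate grid; daily fields are
then averaged into April–June calendar-month means (NaN days excluded
from the denominator). The bound 0 ≤ Pr(Agg) ≤ min(Pr(1), Pr(Agg|1))
holds at every cell; the product identity is a daily-field property
(monthly means of products are not products of monthly means, though the
bound still holds).

Leave-one-year-out evaluation refits a single model per stage per fold
with the same hyperparameters and scores the held-out year, measuring
interannual transferability. Variable importance is the per-member
normalized loss-reduction share (summing to 100), averaged over members;
response curves clamp one covariate along a value grid and average the
ensemble response over the data distribution.

## Indices

For a chosen month (default May), the year × cell stack of monthly-mean
Pr(Agg) maps is reduced two ways:

* **EOF-PC1** — per-cell temporal means removed, SVD of the anomaly
  matrix; cells with any missing year are dropped; PCs are scaled to
  unit variance and each mode's sign is fixed so its PC correlates
  non-negatively with the domain-mean anomaly series. No latitude
  weighting is applied (the domain spans ~3° of latitude; cosine
  weighting is a no-op at that scale and is omitted).
* **Hotspot area** — the count of cells strictly above the pooled
  climatological mean + 2 SD (pooled over all cell-year values of the
  stack; a per-month variant of the baseline is available), normalized
  to zero mean and unit SD across years. Year-by-year counting is used
  because a purely climatological map yields no time series.

Agreement between the two indices is Spearman rank correlation over
overlapping years (≥ 5 required), with a two-sided p from the
t-approximation, or the exact permutation distribution when n ≤ 10.

## Independent evaluation

Observed monthly SST and SSH fields (in synthetic runs, monthly means of
the generated dailies standing in for satellite products) are compared
with the aggregation indices. SLA is SSH minus the per-cell,
per-calendar-month mean over a baseline period (default: all available
years). Per-month EOFs of the observed variables give environmental PC
series; coherence is the same Spearman machinery. Lagged spatial
correlation maps correlate a species' May index with each preceding
month's field (January–May) within every grid cell, flagging p < 0.05
cells with no multiplicity correction (matching conventional
significance contours; an FDR option exists but is off by default).
Per-cell correlation is Spearman for consistency with the index
coherence; the evaluation runs on the observation grid and the index,
being spatially scalar, is never interpolated.

## Synthetic seascape

The generator supplies inputs with the structure the analysis assumes
and known ground truth:

* **Fields.** Daily SST/SSH/currents/wind stress/chlorophyll on the grid
  as smooth cross-shore gradients plus Gaussian-random-field mesoscale
  noise (smoothed white noise, correlation length 3 cells; SST noise SD
  0.25 °C, chl log-SD 0.7). A shared interannual warm/cool mode (one
  index value per year, optionally confined to a subregion mask) shifts
  domain-mean SST by 0.9 °C and SSH by 0.04 m per unit index;
  chlorophyll carries no warm-mode loading, so presence responses and
  aggregation responses to warm years are decoupled by construction.
  Static fields: depth (positive magnitude) increasing offshore,
  great-circle distances to shore (eastern edge) and colony.
* **Effort.** Exactly `visits_per_year` cell-day visits per year,
  uniform over cells and season days (season starts April 1), coverage
  uniform on (0, 1]; repeat visits are separate transects whose coverage
  adds (capped at 1) at gridding.
* **Counts.** Presence is logistic in chlorophyll (coef 1.6 on log chl)
  and distance to shore (−0.025 per km), with an optional
  colony-distance decay for resident central-place foragers. Positive
  counts are rounded lognormals (log-mean 2.0, log-SD 0.6, truncated at
  1) — matching the field reality of heavy right tails where the minimum
  is far below the maximum. A fraction of visits are *patch encounters*
  whose log-mean is boosted by 3.0; the patch log-odds follow
  logit(0.07) + 1.4·(log chl − 0.7) + `agg_forcing`·warm index. Shifting
  patch probability rather than all counts preserves the median while
  inflating the upper decile — exactly the quantity the cutoff labels.
  The patch base rate sits below 10% so the top-decile cutoff falls
  between the background and patch count modes, making aggregation
  labels predictable from covariates; `agg_forcing` (default ±1.2)
  controls the sign and strength of the species' aggregation response to
  warm years. Behavior labels are drawn independently of count (flying
  fraction 0.3), exercising the behavior filter without coupling.

What the generator does **not** emulate: ocean dynamics (no advection or
upwelling mechanics), species interactions, observer/sea-state detection
effects, spatial autocorrelation of survey tracks (visits are
independent cell-days, not contiguous transects), and seasonal cycles
within the survey window. Passing recovery tests therefore demonstrate
that the pipeline's statistics recover known structure of this class,
not that real survey data satisfy these assumptions.

## Problem sizes and numerical choices

Desk-scale experiments use deliberately small configurations, stated
here as the package's own study design:

* Fixture runs: 10×10 grid, 6 years (one failing the 50-record filter),
  2 species with opposite forcing signs, 3-member ensembles, 60-tree
  cap. Completes in seconds; used for the hurdle-bound and determinism
  checks.
* Sign-recovery Monte Carlo: 20×20 grid, 16 years × 61 days, 450
  visits/year, 6-member ensembles with learning rates 0.1/0.05 and a
  150-tree cap (faster-learning, scaled-down stand-ins for the
  50-member/0.01-rate production configuration), May-only hindcast;
  10 runs each with positive and negative forcing.
* Null calibration: 500 cells × 20 years of independent noise; the
  significant-cell fraction is judged against the binomial 95% band
  around 0.05 — a test that, being a 95% band, itself fails for ~5% of
  seeds even under perfect calibration (the per-cell rejection rate of
  the t-approximation measures 0.051 at n = 20).
* Index agreement: 15×15 grid, 18 years, one imposed hotspot mode whose
  amplitude (1 ± 0.5) varies by year — always present so the hotspot
  count varies continuously rather than collapsing to tied zeros.

Every generator and fit is a pure function of its arguments and a seed;
pipeline stages derive their seeds by hashing (master seed, stage name),
so stages rerun independently reproduce their outputs. Degenerate inputs
fail loudly: single-class stages, zero-variance fields (EOF and hotspot
thresholds undefined), fewer than 3 years for EOFs, fewer than 5
overlapping years for index comparison, fewer than 10 positives for a
cutoff.

## Known limitations

* The lognormal-with-patches count law is a stand-in: no quantitative
  distributional family is identified for real transect counts. It is
  isolated behind `SpeciesSimConfig`.
* Coverage-fraction semantics ("5% survey coverage") are operationalized
  as surveyed-area fraction carried on the effort table; other
  operationalizations (e.g., track-length based) would shift which cells
  the filter drops.
* No spatial blocking in cross-validation: random splits share
  cell-days between train and test, so random-split AUC is optimistic
  relative to LOYO — which is why LOYO is reported alongside.
* TSS maximizes over thresholds, which is upward-biased on small test
  sets (visible as slightly positive null TSS).
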