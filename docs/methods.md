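# Methods

`forestagb` estimates plot-level forest total and component aboveground
biomass (AGB) from area-based airborne LiDAR metrics. This note records the
models, the numerical choices, and what the synthetic study does and does not
demonstrate.

## Allometric biomass model

Tree-level total AGB follows the species-specific power law

    M = a0 · D^a1 · H^a2        [kg; D = DBH in cm, H = height in m]

with published coefficients for *Larix gmelinii* (larch) and *Betula
platyphylla* (birch). Components come from proportion functions
`g1, g2, g3` (bark, branch, leaf relative to a stem mass of 1), each a power
law in D and H:

    f_stem = 1/(1+g1+g2+g3),  f_bark = g1/(1+Σg),  f_branch = g2/(1+Σg),  f_leaf = g3/(1+Σg)

so stem+bark+branch+leaf = total exactly (enforced to 1e-9 relative). Two
known defects of the published table are handled explicitly:

* the larch leading coefficient is printed without a decimal point; we adopt
  **0.060848** (the alternative 0.60848 puts one 20 cm stem at ~1.4 Mg, an
  order of magnitude above the plot-level biomass the same source reports);
* the birch total-AGB exponents (0.10850 on D, 0.52019 on H) yield < 1 kg for
  mature stems and are almost certainly misprinted. They are implemented **as
  published**; all coefficients are overridable via `SpeciesCoefficients`.
* the stem-proportion denominator is printed as `g1+g2+g3`; we use
  `1+g1+g2+g3`, the only reading under which the four components partition the
  total, consistent with the g-definition "relative to stem biomass of 1".

Plot AGB sums the per-tree components over stems with DBH ≥ 5 cm (the
inventory censoring threshold, applied at aggregation so censoring
sensitivity is testable) and normalizes by plot area: Mg/ha.

## LiDAR metrics (56-feature registry)

Computed per plot from a height-normalized cloud; only returns strictly above
the 2.0 m cutoff enter height statistics:

* 15 height percentiles `H_p` (p ∈ {1,5,10,20,25,30,40,50,60,70,75,80,90,95,99}),
  linear interpolation between order statistics;
* 15 accumulated-interval-height percentiles `AIH_p` (same p): sort heights
  ascending; `AIH_p` is the first order statistic at which the running height
  sum reaches p% of the total height sum;
* 11 moment/summary metrics: mean, quadratic mean √(mean z²), sd (ddof 1),
  CV, moment skewness m₃/m₂^1.5, non-excess kurtosis m₄/m₂², median absolute
  deviation from the median, mean absolute deviation, min, max, median;
* 10 layer densities `d1..d10`: equal bins on [cutoff, max z] (top bin
  closed), each count divided by the **full** clipped return count (ground
  included), so Σdᵢ = above-cutoff fraction and the d-metrics are sensitive to
  canopy cover. The above-cutoff denominator is available as a config option;
* 5 shape metrics: canopy relief ratio (mean−min)/(max−min), % returns above
  cutoff, % returns above the mean canopy height, H_p99−H_p10 spread, CV of
  the 10 layer densities.

The exact composition of the original 56-name list is not published; this
registry is the package's fixed default and is configurable. Decile-style
names (`H_6`, `AIH_30`) are exposed as aliases of `H_p60`, `AIH_p30`.
Metrics whose preconditions fail (no canopy returns; fewer than two points
for dispersion) are NaN; densities are 0.

Normalization subtracts bilinearly interpolated DEM elevation from each
return; every point must fall inside the DEM extent. Clipping keeps points on
the plot boundary.

## PLSR-VIP feature selection

A NIPALS PLS1 fit on centered/unit-variance X and centered y (unit-variance
scaling makes VIP comparable across metrics measured in metres vs ratios).
Variable importance in projection:

    VIP_j = sqrt( k · Σ_h SS_h w_hj² / Σ_h SS_h ),   SS_h = r²(y, c_h)

with unit-norm weights w_h and component scores c_h. Mean VIP² = 1 by
construction; predictors with VIP > 1.0 (strict) are selected, separately per
response (total, stem, bark, branch, leaf). The printed source formula has a
typographical duplication; the implementation uses the standard weight-share
form above, which satisfies the stated all-equal ⇒ VIP = 1 property. The
component count is configurable (default 2); `choose_n_components` minimizes
leave-one-out PRESS with ties to the smaller count.

## Regression and validation

* **RF**: 100 trees, ≤ 15 candidate features per split (clamped to the
  available predictor count). The source sentence pairs "mtry and ntree" with
  "100 and 15"; read literally mtry = 100 exceeds the feature count, so the
  physically realizable reading (ntree = 100, mtry = 15) is the default and
  the literal one remains configurable.
* **SVR**: RBF kernel, C = 1, ε = 0.1; predictors standardized, and the
  response standardized for the fit and back-transformed (an ε-tube of 0.1 on
  raw Mg/ha with C = 1 cannot track a 20–200 Mg/ha response).
* **Mean baseline**: intercept-only reference model.

Metrics: R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² (the printed formula omits the square on
the residual; the standard form is implemented), RMSE, rRMSE = 100·RMSE/ȳ,
MAE. Protocols: LOOCV (n fits; held-out predictions pooled before computing
metrics — per-fold R² is undefined on single observations) and repeated
70/30 random splits (default 10 repeats; per-repeat train/test metrics
averaged; the repeat with the best test R² flagged). A master seed spawns
per-repeat child seeds.

## Synthetic study design

Because the field and flight data are not deposited, a generator supplies
inventories and clouds with the statistical structure the analysis assumes:

* square plots of 40 m / 45 m side; stem density uniform in 400–1400 /ha;
* DBH log-normal (median 14 cm, σ = 0.35) with a per-plot location shift
  uniform on ±0.25 log units (bounded between-plot stand-size variation);
* height H = 1.9·D^0.75·exp(ε), ε ~ N(0, 0.08) — a standard hypsometric
  power law for boreal conifers;
* species mix 90% larch (larch-dominated stands with a birch admixture);
* clouds at 5.6 returns/m²; each return is ground (z ~ N(0, 0.12 m),
  truncated at ±3σ) or canopy, attached to a tree with probability
  proportional to crown area (crown radius 0.11·H), z triangular between the
  crown base (0.45·H) and the tree top with mode at 0.85·H;
* the ground probability is `gf + (1−gf)(1−cover)` with penetration fraction
  gf = 0.25 and cover = 1 − exp(−Σ crown area / plot area), so stand density
  drives canopy cover and hence the density metrics;
* tree positions uniform in the plot (no clustering); clouds are generated
  pre-normalized, with a tilted-plane DEM + raw-z variant available to
  exercise normalization.

The defaults were calibrated once so that the default 200-plot study spans
roughly the 20–204 Mg/ha plot-AGB range of the motivating field campaign
(mean ≈ 75–80, max ≈ 200 across seeds). The generator does **not** simulate
occlusion, multiple returns, intensity, stem clustering, or allometric error,
and tree height alone drives the crown model — so passing recovery tests
show the pipeline's internal consistency (metrics carry the biomass signal
the generator encodes), not field accuracy. Headline field results (e.g. RF
LOOCV total-AGB R² = 0.75) are qualitative references only and are not
reproduced here; on the cleaner synthetic world the pipeline scores higher
(R² ≈ 0.9).

## Mapping

The normalized scene cloud is gridded (default 25 m cells; the tests use
10 m on single plots), each cell's 56 metrics are computed exactly as for a
plot, and per-component RF models predict cell by cell; cells with fewer than
10 returns are masked. Components are predicted independently, so component
maps need not sum to the total map; a `sum_minus_total` diagnostic layer is
emitted. Negative predictions are clipped to 0 by default. Rasters are
written as ESRI ASCII grids; clouds as XYZ text — plain-text formats chosen
so every product is inspectable and portable.

## Problem sizes and numerics

Tests run the default study at 200 plots (≈ 9 000 returns per plot), chosen
as the size at which LOOCV-vs-split comparisons stabilize while the full
suite stays fast. Component-sum conservation is enforced at 1e-9 relative;
brute-force metric cross-checks at 1e-9 relative; PLSR deflation stops with a
clear error when the residual covariance norm falls below 1e-12 (rank
exhausted). Degenerate inputs (treeless plots, constant responses,
zero-variance predictors, empty canopy) are either handled with documented
NaN/0 conventions or rejected with specific errors.
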