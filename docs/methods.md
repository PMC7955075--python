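# Methods

This note documents the models, conventions and design choices behind
`pavuln`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The assessment model

The unit of analysis is a protected area (PA), represented as a non-empty
set of cells on a declared planar grid (row 0 northernmost; no CRS
handling). Three vulnerability indices are computed per PA:

**Species.** A species "occurs" in a PA iff its range shares ≥ 1 cell with
it — the presence test a polygon overlay would give at the grid's
resolution. Occurring species contribute weights by IUCN category,
VU = 2, EN = 4, CR = 8 (a geometric progression emphasising the most
threatened class; configurable). Scores are computed per taxon group and
cumulatively; the cumulative score is exactly the sum of the five group
scores.

**Anthropogenic.** ΔHFP = zonal-mean HFP(later epoch) − zonal-mean
HFP(earlier epoch). The sign convention makes *increasing* human pressure
positive, matching the index's meaning (high vulnerability = pressure has
grown); the raw wording of the source procedure ("subtract 1993 with
2009") is ambiguous and we resolve it in favor of the stated
interpretation. Zonal means are unweighted averages over a PA's
non-NODATA cells; a fully-NODATA PA yields an explicit NaN, never a
silent zero.

**Climate.** Monthly climatologies (cell-wise mean over an epoch's years,
per month) feed the six bioclim variables. Monthly mean temperature is
(tmin + tmax)/2. MAT is the mean of the 12 monthly means; MAP the *sum*
of the 12 monthly precipitation means (annual total, despite the "mean
annual precipitation" label — the standard bioclim convention). A quarter
is any of the 12 wrap-around windows of 3 consecutive months; MTWQ/MTCQ
are the mean temperature of the warmest/coldest window, PWQ/PDQ the
precipitation sum of the wettest/driest window, ties broken by earliest
starting month (argmax/argmin order), which makes the derivation
deterministic. A single PCA is fitted on the pooled past+present per-PA
table — one coordinate system for both epochs, without which displacement
would be meaningless — after centering and unit-variance scaling (the
columns mix °C and mm; unscaled PCA would be dominated by precipitation;
an `scale=False` flag exposes the unscaled variant). Climate
vulnerability is the Euclidean distance between a PA's past and present
(PC1, PC2) positions.

Each raw column is min–max normalized across PAs. A constant column
normalizes to all zeros with a warning: it carries no ranking information,
and zero (lowest vulnerability) is the conservative reading.

## Hotspot inference

The null model shuffles the observed score vector across PAs (a full
permutation, i.e. sampling without replacement) `n_iter` times; a PA's
exceedance count is the number of iterations in which its observed score
*strictly* exceeds the permuted value it received (ties do not count, so
an all-equal vector can flag nothing). Hotspot thresholds are
`ceil((1−α)·n_iter)` one-tailed and `ceil((1−α/2)·n_iter)` /
`floor((α/2)·n_iter)` two-tailed — 950 and 975/25 at the defaults
n_iter = 1000, α = 0.05. The reported per-PA p is
`1 − exceed_count/(n_iter+1)`.

Two consequences worth knowing:

* Under a full-vector permutation each PA's null is the *marginal* score
  distribution, so its flag depends (in expectation) only on its rank
  fraction (rank − 1)/n. The flags therefore converge, as n_iter grows,
  to the empirical top-α quantile rule — a property the tests exploit as
  an independent oracle.
* Because the null includes every observed score, at most ≈ α·n PAs can
  be flagged regardless of signal strength, and a PA whose rank fraction
  sits exactly at 1 − α has a ~50% flag probability at any n_iter.
  Recovery experiments should plant strictly fewer than α·n signals.

Levels: a PA flagged by all three indices (cumulative species index by
default) is Level 1; two → Level 2; one → Level 3; none → Level 4. The
assignment partitions the network and Level 1 equals the triple
intersection of the hotspot sets. No multiple-testing correction is
applied across PAs (deliberately, matching standard practice for this
null-model approach). Overlap reports give counts and all three
percentage denominators (union, first set, second set).

## Comparison statistics

**Bootstrap contrasts.** Hotspot vs. coldspot differences in a change
variable use a percentile bootstrap: each replicate resamples each group
with replacement at its own size; the interval is the (α/2, 1−α/2)
percentile range of replicate mean differences (90% by default, 1000
replicates). We report the observed difference, the interval, an
interval-excludes-zero significance flag, and a two-sided bootstrap p
(twice the smaller tail fraction of replicates on either side of zero) —
the CI and the p answer slightly different questions and both appear in
the source practice. A point-pair variant (difference of one random
hotspot and one random coldspot value) was considered and not implemented;
the group-mean contrast is the documented default.

**Modified t-test.** The Pearson r between two per-PA variables is the
ordinary coefficient; only its significance is corrected. Pairwise PA
centroid distances are stratified into 10 equal-width classes over
(0, max distance] (classes with < 2 pairs are dropped); within class k the
autocovariance of each centered variable, scaled by its biased variance,
gives ρ̂(k); then

    σ̂ᵣ² = [n + Σₖ Nₖ ρ̂ₓ(k) ρ̂ᵧ(k)] / n²,   m̂ = 1 + 1/σ̂ᵣ²,
    t = r √((m̂−2)/(1−r²)),  p from Student's t with m̂−2 (continuous) df,

with Nₖ the ordered-pair count of class k. The plug-in estimator can
return σ̂ᵣ² < 1/n (or ≤ 0) on finite samples, which would claim more
information than n iid observations; we clamp σ̂ᵣ² ≥ 1/n so m̂ ≤ n + 1 and
the correction degrades gracefully to the classical test. PA location is
the centroid of its cell set. |r| ≈ 1 and m̂ ≤ 2 take warned degenerate
paths (p = 0 and p = NaN respectively).

## The synthetic landscape

The generator produces the conditions the analysis assumes, not the real
geography. Defaults (a scenario is a frozen dataclass, fully determined by
its seed):

| parameter | default | rationale |
|---|---|---|
| grid | 50×50 cells | desk scale; ~6× PA coverage at 100 PAs |
| PAs | 100 disjoint, connected, 4–16 cells | greedy accretion with rejection, mirroring non-overlapping reserves |
| species | 10/9/13/5/298 per group | the study system's 103/86/134/50/2983 pool scaled ~10× down |
| category mix | VU .5 / EN .3 / CR .2 | threatened-class frequencies decline with severity |
| field autocorrelation | 5 cells | Gaussian low-pass of white noise, periodic boundary; realized mean/sd rescaled exactly |
| warming trend | 1.3 °C | magnitude of the region's observed 1960s→2010s warming |
| warming spatial CV | 0.25 | warming varies regionally; cell-mean shift stays exactly at the trend |
| HFP | mean 12, sd 6, clamped [0, 50] | the published footprint scale is bounded |
| HFP epoch increment | +2.5 ± 2.5 | puts ~¼ of PAs above a ΔHFP of 4, the reported landscape feature |
| epochs | 10 years each | two 10-year windows |

Species ranges grow by seeded region accretion (guaranteed contiguous,
free to overlap each other and PAs). Planted hotspots inflate a chosen
signal in chosen PAs: extra CR species confined to the PA (species), a
footprint boost of multiplier × the ΔHFP spread (anthropogenic), or a
+multiplier × 0.5 °C present-epoch warm anomaly (climate).

What the generator does *not* emulate: real range-map shapes and
range-size distributions, elevation-driven climate gradients, irregular
PA geometry, area-weighted (partial-cell) zonal statistics, and any
correlation between species richness and human pressure beyond what the
planted signals induce. Passing tests therefore demonstrate correctness of
the machinery and calibration of the inference under the stated
statistical structure — not that the real system's headline numbers are
reproduced, which would require the external national datasets.

## Numerical and I/O choices

* All generators and tests are pure functions of (parameters, seed);
  pipeline stages draw per-stage seeds spawned from one master seed, and a
  run's manifest records them, so identical configs give byte-identical
  outputs.
* Degenerate inputs: sd = 0 fields are constant; constant score vectors
  warn and flag nothing; zero-variance PCA columns get scale 1 with a
  warning; empty bootstrap groups are errors, singletons warn.
* Rasters are ESRI ASCII grids (text); PA footprints GeoJSON polygons
  (cell-square unions, read back by cell-center containment, overlap
  rejected with the offending pair named); monthly climate cubes one
  JSON-headed whitespace-matrix text file; tables CSV (UTF-8, comma,
  header mandatory); configs/reports/manifests JSON.
* Problem sizes in the test suite (e.g. 2,000 PAs × 20 seeds for null
  calibration, 200 replicates for the correlation-test calibration,
  500 simulations for bootstrap coverage) were chosen to give stable
  Monte-Carlo estimates while keeping the whole suite in well under a
  minute per file on one CPU.

## Known limitations

* The permutation null is non-spatial; spatially constrained alternatives
  (e.g. torus shifts) are out of scope.
* The exact variant of the spatially corrected t-test used by legacy
  macroecology software is unspecified; ours is the
  distance-class CRH-style estimator documented above, with the class
  count exposed as a parameter.
* Min–max normalization is sensitive to single extreme PAs; ranks are
  preserved (the normalization is strictly monotone) but spacing is not
  robust.
* The species index counts presence only; range-size weighting and
  verification against PA inventory reports are not implemented.
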