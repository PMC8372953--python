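# Methods

`forestcarbon` implements the analysis chain of a community-forest carbon
study: a plot census is summarised and classified into forest types, tree
biomass is estimated allometrically and converted to carbon, land-cover
change between two map dates is accounted and projected forward with a
CA-Markov model, and the resulting carbon-stock trajectory is valued on the
voluntary carbon market. This note records the models, their assumptions,
and the design choices that were genuinely open.

## Inventory and structure statistics

A census record is one stem with DBH ≥ 5 cm (the standard tropical-census
threshold; smaller stems are rejected at read time and counted in the log).
Plots default to 0.16 ha (40 m × 40 m), optionally subdivided into 16
subplots of 10 m × 10 m.

* Density and basal area divide totals by total surveyed area; per-tree
  basal area is π(DBH/200)² m² with DBH in cm.
* Shannon–Wiener diversity uses log base 2 (H′ in bits, bounded by
  log₂ richness). A different base can be passed explicitly.
* The importance value index per species is the sum of relative density
  (stem share), relative frequency (share of occupied quadrats, summed over
  species), and relative dominance (basal-area share). Two normalisations
  are offered: `standard_300` (each component sums to 100, IVI to 300) and
  `paper_100` (components divided by 3, IVI sums to 100). The second exists
  because published tables in this study system normalise to 100; it is the
  default so per-plot IVI rows are directly comparable. Frequency uses the
  subplot quadrat when all records carry subplot ids, else the plot.
* Species overlap: the Jaccard index proper (shared/union) plus a
  `paper_total` variant (shared / a reported overall species count), kept
  because published overlap figures are sometimes computed that way. Only
  `standard` is a true Jaccard index.
* Size-class distributions use half-open `[lo, hi)` classes (default DBH
  edges 5/10/20/30 cm, height edges 1.3/5/10/15 m, last class open).
  Boundary ownership is a convention, not a fact about the data; lower-
  inclusive was chosen for determinism. Sub-threshold records go to an
  explicit below-range bucket.
* One-way ANOVA of per-plot metrics delegates to `scipy.stats.f_oneway`;
  all-identical input is reported as F = 0, p = 1 rather than NaN.
* Sampling intensity n = ⌈(Zσ/E)²⌉ rounds up — the conservative choice when
  the source convention is unstated.

## Forest typing

Plots are clustered on their per-plot IVI profiles (rows sum to 100) with
Euclidean distance. Ward linkage is the default: it is the linkage
consistent with reading "information remaining" as a within-group
sum-of-squares budget. Average, complete, and a hand-written Lance–Williams
flexible-beta (β = −0.25) linkage — the classic default of PC-ORD-style
vegetation software, absent from scipy — are available.

"Information remaining" after a merge step is computed exactly, not from
linkage heights: the partition at each step is replayed and
100 × (1 − within-group SS / total SS about the grand mean) is reported.
This makes the curve well-defined for every linkage. Cutting at p% selects
the coarsest partition retaining at least p%. The chaining diagnostic is the
percent of merges that attach a singleton to a group of size ≥ 2.

Degenerate data (duplicated rows) merge at height 0 and any cut returns the
duplicated groups; ties in the flexible-beta merge order break toward the
lowest cluster-id pair.

## Allometric biomass and carbon

Per-tree biomass uses the Ogawa allometry for Thai deciduous forests
(D in cm, H in m, outputs kg):

    Ws = 0.0396 (D²H)^0.9326
    Wb = 0.003487 (D²H)^1.027
    Wl = 1 / (28.0/(Ws+Wb) + 0.025)

The leaf formula is the reciprocal form with a 1/0.025 = 40 kg asymptote;
the alternative reading of its (often badly typeset) source expression,
28/Ws + Wb, is dimensionally incoherent and is not implemented. Coefficients
live in a config mapping so other allometries can be swapped in.

The allometry is applied per tree in kg and aggregated: per-plot t ha⁻¹ =
Σ kg / 1000 / plot area; stratum summaries are mean ± sample SD (n−1) over
plots (plot-level SDs assumed, matching how plot-based inventories report
spread); the overall mean weights plots equally, which for equal-area plots
equals the plot-count-weighted pooling of stratum means. Carbon = 0.47 ×
biomass (IPCC default carbon fraction, configurable) at every level, so the
carbon/biomass ratio is exactly the configured fraction at tree, plot,
stratum and landscape scale.

## Land-cover change and CA-Markov projection

Maps are categorical grids (plain-text integer rasters, row-major from the
top-left, nodata −1). Change between two dates partitions cells into
degraded (forest → non-forest), restored (non-forest → forest), retained
(forest → forest) and retained-non-forest, given a forest/non-forest split
of the legend.

The transition matrix is the row-normalised two-date cross-tabulation;
classes absent at the first date get an identity row. One Markov period is
the observed inter-date interval treated as a single step; projections k
periods ahead are aᵀPᵏ, which conserves total area exactly.

Spatial allocation (`ca_allocate`) is deliberately deterministic, since the
reference implementations of CA-Markov are undocumented black boxes:
per-class cell targets come from the Markov projection rounded by largest
remainder (total conserved exactly); a cell's suitability for class c is the
fraction of class-c cells in the (default 5 × 5) window around it on the
current map; classes below target claim cells from classes above target in
globally descending suitability, ties broken by row-major cell order then
class order; unclaimed cells keep their class. The `seed` parameter exists
for interface symmetry and has no effect.

Accuracy assessment: overall accuracy = trace/total of the confusion matrix;
Cohen's kappa = (p₀ − p_e)/(1 − p_e) with p_e from the marginals; a
single-class comparison (p_e = 1) is degenerate and reported as kappa = 1.
An NDVI helper ((NIR − red)/(NIR + red), NaN when both bands are zero) is
provided for workflows that derive the forest mask from imagery; image
classification itself is out of scope — the pipeline accepts any
pre-classified map.

## Carbon ledger and market valuation

Per-class carbon = area × carbon density (t C ha⁻¹); densities are inputs
(from the biomass stage, a config, or back-computed from a published table
via `densities_from_stocks`). Period changes report Δ t C, percent of the
starting stock, and annualised variants (Δ/years; the percent uses the
starting stock as base). CO₂-equivalent uses 3.67 t CO₂e per t C (44/12)
and valuation a voluntary-market price (default US$3.20 per t CO₂e);
currency is unrounded internally.

The packaged reproduction tables carry one internal inconsistency of their
source, preserved as-is: the 2038 grand-total carbon stock (247,475 t C)
exceeds the sum of its class rows (230,478 t C = 0.47 × the consistent AGB
total). Class-row sums are used everywhere except the 30-year annualised
rate, which is only reproducible from the grand totals; `reproduce.py`
documents the switch. Similarly, the published degraded-area "average annual
rate" row mixes a positive magnitude with a negative percent; the ledger
reports signed deltas throughout and does not reproduce that row.

## Synthetic data

The generators define the validation conditions:

* **Stands** — 25 plots × 0.16 ha, 150 stems per plot (≈ 940 trees ha⁻¹),
  a 110-species pool with log-series ranked abundances (x = 0.98; a
  geometric series is available), DBH = 5 cm + Exponential(rate 0.13 cm⁻¹)
  — the simplest generator with the reverse-J size structure and a ≈12.7 cm
  mean DBH — and height = 2.0·DBH^0.6 with multiplicative lognormal noise
  (σ = 0.15), giving ≈ 9 m mean height. One integer seed drives all draws.
  These defaults mirror the reported stand the package targets; they are
  not fitted to any test outcome.
* **Landscapes** — raw date-1 cells iid from given class proportions; raw
  date-2 cells pushed through a known row-stochastic matrix independently
  per cell; both grids then receive the same number of 3 × 3 majority-
  smoothing passes (ties keep the current class; edges truncate). Smoothing
  is applied to the raw pair, not sequentially, so an identity matrix yields
  an identical pair under any smoothing. With zero passes the per-cell draws
  are exactly multinomial and the estimated transition matrix converges to
  the truth (checked at ±0.03 on a 100 × 100 grid).

What the generators do **not** emulate: spatial clustering of species,
DBH–height correlation beyond the mean allometry, measurement error,
spectral/radiometric properties of imagery, topography, and real landscape
geometry. Passing tests therefore demonstrate correctness of the estimators
and allocators under known ground truth, not field accuracy.

## Problem sizes and numerics

Validation uses 100 × 100 (recovery) and 80 × 80 (allocation) grids and
stands of 10–25 plots; the whole suite runs in seconds. Largest-remainder
rounding breaks remainder ties toward lower class index; information-
remaining for zero-variance data is defined as 100% until the final merge;
all percent quantities are reported on the 0–100 scale. Reruns under a
fixed config and seed are byte-identical (the run manifest stamps the
config hash and seed and omits wall-clock timings).

## Known limitations

Below-ground, deadwood, litter and soil carbon pools are out of scope, as
are height imputation, taxonomy resolution, rarefaction-style diversity
estimators, image classification, CRS handling/GeoTIFF I/O, price modelling
and uncertainty propagation on market values. The flexible-beta agglomerator
is O(n³) and intended for plot-scale inputs (tens to hundreds of rows).
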