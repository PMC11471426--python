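# Methods

This note documents the models and procedures implemented in
`climniche`, the synthetic study system they are validated against, the
parameters that matter, and the numerical choices made where the design
was genuinely open.

## Occurrence quality control

Filters run in a fixed order: year window (1981–2018 inclusive, records
with no year removed) → known-range distance (records ≥ 200 km from the
species' range polygon removed, when a polygon is supplied; distance to
a point inside a polygon is 0) → centroid proximity (records strictly
within 300 m of any jurisdiction-polygon centroid removed — such
coordinates are a signature of geocoded-to-centroid records) →
taxonomic grouping (species relabelled to group ids) → cell
deduplication (one record per species per grid cell) → modelable gate
(strictly more than 50 retained records).

Open choices, fixed here: the cell-dedupe tie-break retains the record
with the earliest year, then the lexicographically smallest source
label, then input order — fully deterministic and auditable. "Within
300 m" is strict (<); "≥ 200 km" is inclusive. All distances are
Euclidean in the planar km coordinate system. The QC report conserves
counts (input = retained + Σ removed) per stage; note that per-species
accounting changes label when grouping relabels species, so
conservation is asserted at the cohort level in tests. The pipeline is
idempotent: running it on its own output changes nothing.

## Modelling

The central objects follow the statsmodels convention:
`ClimateNicheModel` (data + options) → `fit(seed)` →
`NicheEnsembleResults` (estimates, uncertainties via held-out TSS,
diagnostics, `summary()`, projection methods).

**Predictors.** 24 monthly climate variables (mean temperature and
precipitation, January–December). Elevation and other topographic
variables are deliberately excluded from the predictor set; elevation
enters only the reporting stage (elevation-shift summaries).

**Pseudo-absences.** Presence-only data require background samples:
two replicates drawn uniformly at random without replacement from grid
cells, excluding known presence cells (avoids label noise at desk
scale; with 50 000 background points on a continental grid the
distinction is immaterial, at test scale it is not).

**Run design.** Per technique: 2 pseudo-absence replicates × 2 random
70/30 presence/background splits = 4 runs; with the full 8-technique
registry that is 32 single models, plus one ensemble, per species.

**Techniques.** The registry must contain a linear-logistic learner, a
tree-ensemble learner and the bespoke surface range envelope; five
further analogues are registered for the full design:

| name | implementation |
|------|----------------|
| GLM  | logistic regression on (x, x²) — the customary second-order polynomial niche GLM; a purely linear logistic cannot represent a unimodal climate response |
| RF   | random forest, 100 trees |
| SRE  | surface range envelope (below) |
| ANN  | single-hidden-layer perceptron (16 units) |
| CTA  | classification tree (depth ≤ 8) |
| FDA  | linear discriminant analysis |
| GAM  | cubic-spline basis (5 knots) + logistic |
| MARS | hinge basis at quantile knots + logistic |

The default desk-scale technique set is (GLM, RF, SRE).

**Surface range envelope.** Fitted on presences only: per variable,
the [q, 1 − q] quantile interval of training-presence values
(linear-interpolation quantiles); a cell scores 1 iff every variable
falls inside its interval. Default q = 0.025. SRE members contribute
their binary scores to the ensemble mean.

**Evaluation.** TSS = sensitivity + specificity − 1 at the threshold
maximizing sensitivity + specificity, swept over the sorted unique
predicted values with the rule "suitable iff score ≥ threshold"; ties
break toward the smaller threshold. Constant predictions are flagged
degenerate and scored 0.

**Ensemble.** Members are single models with TSS strictly above 0.7;
at least three are required (otherwise the species is flagged
non-ensembleable). Weights are TSS-proportional and sum to 1 — the
simplest faithful reading of a "weighted means" combination, logged in
the run manifest. The ensemble is evaluated on the pooled held-out
data of all runs; the threshold found there is the species' single
binarization threshold, reused across all scenarios so that maps are
comparable over time.

**Variable importance.** Permutation importance on the ensemble: for
each variable, 1 − Pearson correlation between predictions on the
original feature matrix and on the matrix with that column permuted,
averaged over `n_perm` permutations and clipped to [0, 1]. With
strongly correlated monthly predictors (the realistic default),
importance legitimately spreads across correlated neighbours of the
truly used variable; identifiability tests therefore use a grid
configuration with nearly independent months and short autocorrelation.

## Projection and range change

Projection applies the weighted-mean prediction cell-wise to any
scenario grid; it is deterministic and cell-order equivariant. No
extrapolation masking is applied for climates outside the training
envelope (a known limitation, see below). Binarization uses
mask = values ≥ threshold (inclusive boundary, deterministic).

Range-change accounting between two binary maps: Loss, Gain, Maintain
cell counts; percent lost = 100·Loss/(Loss+Maintain); percent gained
= 100·Gain/(Loss+Maintain); range change = percent gained − percent
lost, which equals the net percent change in range size. Percentages
are carried unrounded and rounded to 2 decimals only at output — the
published reference table bundled with the package can only be
reproduced this way (e.g. the Sierra Gartersnake row's −75.15 differs
from the rounded-first −75.16).

Classification: net change ≥ +10 % with turnover ≤ 50 % → expand; the
same growth with higher turnover → shift; net change ≤ −10 % →
contract; a stable-sized range whose centroid moved more than 100 km
(configurable; no published value exists) → stable_shift; else stable.

Centroids are the unweighted mean of suitable cell centers (binary
maps carry no abundance to weight by); shifts are Euclidean distance
in km with bearing clockwise from grid north. Richness maps stack and
sum binary masks; richness change subtracts them, with a no-dispersal
mode that masks each species' gains outside its recent range (so
no-dispersal change is nowhere positive).

## Jurisdiction summaries

Presence in a state requires strictly more than 50 suitable pixels
inside it. Gained / lost / maintained states per species follow from
presence in the two scenarios. Elevation shift within a state compares
the [q25, q75] elevation intervals of suitable cells between scenarios
(linear-interpolation quantiles): disjoint-and-higher → increase,
disjoint-and-lower → decrease, overlapping → similar; the reported
median change is q50(future) − q50(recent). Cells are assigned to
states by cell-center containment; centers exactly on a shared edge go
to the lexicographically first state.

## Synthetic study system

The generator emulates the structure of interpolated monthly
climatologies on a planar equal-area km grid (cell_size = 1 emulates a
1-km grid; all distances Euclidean in this plane):

- **Temperature** per month = mean (8 °C) + sinusoidal annual cycle
  (amplitude 12 °C, coldest in January) − latitudinal gradient
  (0.05 °C/km northward) − lapse rate (6.5 °C per km of elevation)
  + smooth Gaussian random fields (an annual field, SD 2 °C, shared by
  all months, plus per-month fields, SD 0.8 °C), each smoothed to a
  configurable autocorrelation length (default 10 km) — so models face
  spatially and seasonally correlated predictors, as in real data.
- **Precipitation** per month = 60 mm × exp(smooth fields) × a
  winter-wet annual cycle; positive by construction.
- **Elevation** = 500 m + 800 m relief (smooth field) + a northward
  rise (3 m/km), coupled to temperature through the lapse rate.
- **Scenarios.** Six labels (past, recent, mid45, mid85, late45,
  late85). Each non-recent scenario applies a constant temperature
  offset and precipitation multiplier to the recent baseline
  (defaults: past −1 °C; mid-century +1.5/+2 °C; late-century
  +2/+3 °C with multipliers 0.97–0.90 — a moderate/high-emission
  spread with mild drying). No published values exist for these
  deltas; they are config, and scenario contrasts are exact by
  construction (a +3 °C offset shifts every layer mean by exactly 3).
- **Virtual species.** Suitability = product of Gaussian responses,
  one per selected variable; optima placed at configurable quantiles
  of the reference grid's variable distribution, breadth a fraction of
  the variable's spatial SD (default 0.25 — narrow enough that the
  presence/background contrast is resolvable; at ~0.5 SD the two
  distributions overlap so heavily that no classifier, including an
  oracle on the true suitability, separates them). The "truly
  suitable" region is the top `prevalence_target` fraction of recent
  cells; the same absolute suitability cut defines truth on other
  scenarios.
- **Occurrences** are sampled with probability proportional to true
  suitability, uniform within the cell, years uniform on 1981–2018,
  plus injected defects at configurable rates: duplicate-cell records,
  missing years, records snapped within 300 m of a jurisdiction
  centroid, and far outliers placed ≥ 200 km outside the true-suitable
  convex hull. Each record carries its ground-truth artifact label so
  QC filters are validated against known truth.
- **Jurisdictions** are a Voronoi partition of random seed points —
  irregular, state-like, and trivially a tiling.

All generators are pure functions of (config, seed).

### Recovery experiments

Two standing experiments validate the full pipeline against known
truth, at sizes chosen to keep a desk run in minutes:

- **Niche recovery** — five 200×200-cell climate realizations, one
  virtual species each (prevalence 0.15, breadth 0.2 SD, optima spread
  over the 0.35–0.65 quantiles), 500 presences, 2 × 2000
  pseudo-absences, techniques (GLM, RF, SRE). Checks: median held-out
  ensemble TSS ≥ 0.7 and median Jaccard overlap between the recovered
  binary map and the true suitable region ≥ 0.6. Prevalence 0.15 is
  deliberate: at higher prevalence the truth mask carries a broad
  low-suitability fringe that sampled presences cannot support, and
  Jaccard measures that fringe rather than model skill.
- **Directional recovery** — a thermally limited species (single
  temperature response, optimum at the 0.45 quantile, breadth 0.15 SD)
  on a domain rising 10 m/km northward with weak free temperature
  noise, so temperature is nearly determined by latitude and
  topography and a thermal niche maps onto a narrow elevation band;
  precipitation is held at baseline so the experiment isolates the
  +3 °C signal. Checks over 10 seeds: the recovered niche's centroid
  moves north and the within-state elevation IQR shifts significantly
  upward, each in ≥ 80 % of seeds. The optimum sits at q0.45 rather
  than deeper in the cold tail because a +3 °C shift from the tail
  pushes the niche core outside the climates present on the grid and
  the fixed recent-scenario threshold then (correctly) yields empty
  future maps.

### What the synthetic system does not emulate

Real occurrence data carry spatially biased sampling effort,
positional error, detection failure and taxonomic drift; real climate
surfaces carry orographic structure, coastlines and inter-variable
physics beyond a lapse rate; real niches are shaped by biotic
interactions and dispersal history. Passing recovery tests therefore
demonstrates that the pipeline's machinery is correct and that its
statistics behave as designed — not that its projections for any real
species are accurate. Paper-scale empirical results (continental
richness patterns, mean shift distances, agreement with published
range maps) require the real occurrence and climate datasets and are
out of scope here.

## Numerical choices and degenerate inputs

- Quantiles everywhere use numpy's linear-interpolation convention.
- Threshold sweeps visit the sorted unique predicted values; ties in
  sensitivity + specificity break toward the smaller threshold.
- Degenerate (constant) predictions: TSS 0 with a `degenerate` flag;
  permutation importance returns all-zero scores.
- Empty binary maps: centroid undefined (None); range-change class
  "undefined" when the current range is empty; elevation shift
  "not_comparable" when either within-state suitable set is empty.
- All stochastic steps take explicit seeds; independent streams are
  spawned via `numpy.random.SeedSequence`. The pipeline manifest
  records every seed, threshold and library version; rerunning a
  manifest reproduces byte-identical CSV outputs.

## File formats

Rasters are exchanged as ESRI ASCII grids (.asc, plain text, readable
by any GIS), occurrences as CSV (species, x, y, year, source),
jurisdictions as GeoJSON polygons (built from the cell tiling, with
centroids as properties), configs as YAML, manifests as YAML.

## Known limitations

- No extrapolation masking: projecting to climates outside the
  training envelope trusts each technique's extrapolation behaviour
  (tree ensembles flatten, logistic models extend their gradients).
- The ensemble weighting ("TSS-proportional") and the permutation
  importance algorithm are explicit reconstructions; published
  descriptions of comparable workflows do not pin either down.
- Desk-scale defaults (100×100 grids, 2000 pseudo-absences, three
  techniques) are orders of magnitude below a continental study; the
  CLI's `--paper-scale` flag raises them (50 000 pseudo-absences, the
  full 8-technique registry) but runtimes grow accordingly.
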