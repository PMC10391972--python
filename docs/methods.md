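# Methods

`isomigrate` implements the dual-isotope assignment-to-origin workflow used
in migratory-connectivity studies of birds that molt on their non-breeding
grounds, together with the two downstream summaries that make the
assignments interpretable: spatial clustering of individual probability
surfaces into discrete candidate molt regions, and isotopic-niche overlap
between populations as a proxy for connectivity strength.

## Assignment model

A feather grown at raster cell *x* is modelled as a draw from a bivariate
normal over (δ²H_f, δ¹³C_f):

    y | x  ~  N(μ(x), Σ),   Σ = [[σ_H², ρσ_Hσ_C], [ρσ_Hσ_C, σ_C²]]

μ(x) comes from feather isoscapes: the precipitation δ²H surface passed
through the linear transfer function δ²H_f = 17.57 + 0.95·δ²H_p (fitted for
non-ground-foraging Nearctic–Neotropical migrants), and the plant δ¹³C
surface shifted by a +2‰ plant→insect→feather discrimination.  Both
coefficient sets are parameters of `calibrate_h_isoscape` /
`plant_to_feather_c` so other taxa's calibrations can be substituted.

With a flat prior over cells, the posterior origin probability of cell *x*
is the likelihood normalized over the valid (range-masked) cells.  δ¹⁵N is
never used for assignment — its continental patterning is dominated by
agricultural inputs that are hard to model spatially — only as a niche
axis.

Key parameters and defaults:

| parameter | meaning | default | why |
|---|---|---|---|
| `sd_h` | assignment SD for δ²H_f (‰) | 12 | typical calibration residual SD for feather δ²H |
| `sd_c` | assignment SD for δ¹³C_f (‰) | 1.5 | plant-isoscape residual scale |
| `rho` | isotope correlation | 0 | the two isoscapes are governed by different bioclimatic processes (treated as orthogonal) |
| `level` | odds level for binarization | 2/3 | conservative 2:1 odds ("≥ 66.7%") |

Per-cell predictive SDs are rarely published with isoscapes, so an
`Isoscape` carries either a scalar SD (default) or a full SD raster.

### Odds-ratio binarization

"≥ 66.7% probability" is implemented as a cumulative-mass rule: the
*smallest* set of highest-probability cells whose summed probability
reaches the level is coded 1.  (A per-cell threshold of 0.667 would almost
never fire on a normalized surface with thousands of cells.)  Ties at the
inclusion boundary are broken deterministically in row-major cell order,
so binaries are bit-reproducible.  Because the level is exactly 2/3, the
retained mass always ≥ 66.667% and typically overshoots by about one cell's
probability.  Raising the level can only add cells (monotonicity), and
when data are generated from the assignment model the true origin cell
falls inside the region in ≥ 2/3 of cases up to binomial noise — the
defining calibration property of a highest-density odds region, checked in
the test suite on 500 simulated birds.

## Raster conventions

Grids are row-major with the origin at the top-left cell corner and
cell-center registration; coordinates are planar (no CRS machinery).  Any
pairwise surface operation demands identical shape, origin and cell size
and raises otherwise — silent resampling is the classic isoscape bug and
is deliberately impossible here.  I/O formats are Esri ASCII grid (text)
and minimal single-band GeoTIFF (pixel-scale, tiepoint and nodata tags via
`tifffile`).  Missing values are an explicit mask in memory and a recorded
nodata sentinel on disk, never sentinel numerics inside tables.

## Outlier filtering and grouping

Feathers with δ²H_f strictly below −120‰ are treated as grown on the
breeding grounds (e.g. replaced after feather loss) and removed before
assignment; a value of exactly −120‰ is kept.  Sampling sites can be
collapsed into analysis populations through an explicit site→population
map; unmapped sites are an error rather than a silent pass-through.

## Clustering into candidate regions

* **Schoener's D** between two normalized surfaces: D = 1 − ½ Σ|p₁ − p₂|,
  1 for identical and 0 for disjoint surfaces.
* **Bootstrap**: the resampling unit is the valid raster cell (sampled
  with replacement; surfaces renormalized per replicate).  This is the
  only unit available from single surfaces; the bootstrap SD is reported
  alongside the point estimate, which is always computed on the full
  surfaces.  The conventional replicate count is 1,000; the end-to-end
  driver defaults to 25 replicates, which is plenty to stabilize the
  point-estimate-based clustering at desk scale.
* **Individual clustering**: distance = 1 − Pearson correlation between
  rows of the similarity matrix, average-linkage agglomeration, dendrogram
  cut at height 0.5 (all merges above the cut are broken).  Constant
  similarity profiles have undefined correlations and are assigned
  maximal distance 1.
* **Spatial k-means**: each valid cell's feature vector is the z-scored
  per-individual likelihood profile (PCA-reduced to ≤ 10 components when
  more individuals are present) concatenated with its z-scored planar
  coordinates scaled by `geo_weight/100 · √(feature dim)`.  `geo_weight`
  runs 1–100; 10–20 is the practical range and 15 the default.  The
  weighting construction itself is this package's definition (the tools
  it emulates do not publish theirs); the documented property — higher
  weight never reduces 4-neighbour label contiguity on a seeded
  scenario — is asserted in the tests.  `k` defaults to the cluster count
  the dendrogram cut finds, and is overridable (the worked examples use
  the design's known region count).
* **Zonal membership**: an individual joins the cluster in which its
  probability surface attains its maximum (ties to the lowest cluster id).
  Population × cluster proportion tables summarize connectivity structure.

## Niche ellipses

The "40% ellipse" is the classical 1-SD standard ellipse of the fitted
bivariate normal (containing ≈ 39.35% of its mass), not an exact-40% χ²
contour; SEA = π√(λ₁λ₂), SEAc = SEA·(n−1)/(n−2).  Bayesian uncertainty
uses the conjugate normal-inverse-Wishart posterior with identity prior
scale, 2 prior degrees of freedom and vanishing prior weight on the mean,
sampled directly (no MCMC): Σ | data ~ InvWishart(2 + n, I + S).  Overlap
between two ellipses is computed on 360-vertex polygon approximations
(within 1% of exact for circles).  Because no single overlap convention is
universal, both are reported: intersection/union (primary; symmetric,
bounded) and intersection/smaller-ellipse.  Overlap geometry uses
SEAc-scaled ellipses by default so small samples are not understated.
LDA fusion z-scores the input variables (so ‰ and mm are commensurable),
drops incomplete cases listwise, and uses the first two Fisher
discriminant scores; with only two groups a single discriminant exists and
the second axis is zero-filled, which is degenerate for ellipse fitting —
LDA-based niche comparisons therefore need ≥ 3 groups.

## Synthetic worlds

The generator replaces proprietary continental isoscapes and unpublished
field data with planar worlds whose truth is recorded at cell resolution:

* precipitation δ²H: linear west–east gradient (default 0.8‰/cell from a
  −120‰ base) plus optional smooth Gaussian bumps for texture;
* plant δ¹³C: an orthogonal south–north gradient (0.08‰/cell from −26‰);
* molt regions: named rectangles/discs inside a rectangular range mask;
* populations: each bird draws a true origin cell uniformly from its
  population's region (or region mixture, emulating weak connectivity),
  then its isotopes from the assignment model's own bivariate normal at
  that cell; δ¹⁵N ~ N(population offset, 1‰) and wing length ~ N(per-sex
  mean, 3 mm) have no spatial signal by design; a configurable fraction of
  birds receives a breeding-grown δ²H_f drawn uniformly from
  (−180, −125)‰ so the outlier filter has something to do.

Presets: `strong` (two 50-bird populations in disjoint regions ~45‰ apart
in feather δ²H and 3.2‰ in δ¹³C — a migratory divide), `weak` (two
populations sharing both regions through mixtures), and `three-species`
(three species from one breeding area with partially overlapping regions,
species-level δ¹⁵N offsets and wing lengths).  Sample sizes (50–60 per
population), isotope scales and noise levels sit in the range typical of
feather-isotope sampling campaigns.  All randomness descends from one
seed through named substreams (world, then per population), so partial
reruns are reproducible.

What the generator does *not* emulate: realistic geography or range
shapes, spatial autocorrelation of calibration error, inter-annual
isoscape variation, non-Gaussian heavy-tailed measurement error, and any
spatial structure in δ¹⁵N or wing length.  Passing tests therefore show
the machinery is correct and well-calibrated *under the stated model*;
they do not certify accuracy on real continental isoscapes, where
isoscape misspecification usually dominates.

## Numerical choices

* Densities are computed in log space and normalized after subtracting the
  maximum, so extreme isotope values cannot underflow to an all-zero
  surface.
* Covariance specs are validated for positive definiteness (|ρ| < 1,
  SDs > 0); rank-deficient point clouds are rejected before ellipse
  fitting; a singular pooled within-class covariance aborts LDA with
  advice to drop a collinear variable.
* k-means uses 10 seeded restarts; cluster labels are renumbered 1..k by
  descending size so labellings are stable across runs.
* Problem sizes in tests and the worked examples (100×100 worlds, 2×50
  birds, 25–500 bootstrap/posterior replicates) keep a full run in seconds
  while leaving every statistical check well-powered; the same code scales
  to continental grids by swapping the input rasters.

## Known limitations

* Assignment assumes a flat prior over valid cells; banding or tracking
  priors are not supported.
* The Σ off-diagonal defaults to 0; there is no facility to estimate ρ
  from data.
* Range masks are rasters; polygon ingestion and reprojection are out of
  scope.
* Overlap percentages depend on the chosen denominator; both conventions
  are emitted precisely because published values are often not comparable
  across studies.
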