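# Methods

## Spatial model

The analysis operates on two inputs per case: a tissue-class raster
(integer labels 0 background, 1 tumor, 2 stroma, 3 lymphoid follicle, with
a known µm-per-pixel scale) and a cell table (marker ∈ {CD8, CD20, CD68},
x/y in µm). All geometry uses the raster frame: origin at the top-left
corner, x rightward, y downward, micrometres throughout.

**Hexagonal lattice.** Axial coordinates (q, r); for the default pointy-top
orientation the center of (q, r) at side s is (s·√3·(q + r/2), s·3r/2).
The grid contains every hexagon whose polygon intersects the raster
rectangle. Membership of a point is nearest-center (the Voronoi cell of a
hexagonal lattice is the hexagon itself); boundary ties go to the
lexicographically lowest (q, r), which makes assignment deterministic and
order-independent. Areas are measured by pixel counting — a pixel belongs
to the hexagon containing its center — so per-class areas are conserved
exactly between the raster and the grid, and the statement "the class areas
of a hexagon sum to its intersection with the raster" holds exactly in that
same pixel metric. Polygon-clipped areas would differ from pixel counts by
O(pixel size × perimeter); pixel counting was chosen because it is exact
under aggregation, fast, and converges to the geometric value as resolution
grows.

**Classification and tumor edge.** With tissue = tumor + stroma area,
a hexagon is background when tissue/total < 0.05; an edge candidate when
both tumor/tissue and stroma/tissue ≥ θ (default 0.1); otherwise the
majority tissue class (ties → tumor). The tumor edge (TE) is the edge
candidates plus tumor hexagons with ≥ 1 stroma neighbour in the
6-neighbourhood — the augmentation guarantees a TE band even when the
tumor–stroma transition falls exactly between hexagons. Both θ and the
augmentation are configurable.

**Ranks.** |rank| is the hexagon-lattice graph distance to the nearest TE
hexagon, computed by multi-source breadth-first search over the
6-neighbourhood; sign is + on the tumor side, − on the stromal side,
0 on the TE. Graph distance (not Euclidean µm) is used because the
interface zone is defined in whole hexagon layers. Background hexagons
block traversal by default, so necrosis or glass does not connect distant
tissue regions; hexagons unreachable from the TE keep an undefined rank
and are excluded from all statistics. Ties between multiple TE components
resolve to the minimum distance automatically.

**Indicators.** Per-hexagon density = marker count / analyzed-tissue area
(mm²); hexagons with < 10⁻³ mm² of analyzed tissue are excluded as
numerically unstable denominators. The rank statistic q(r) is the mean of
per-hexagon densities at rank r (a pooled count/area variant is available
behind `pooled_rank_statistic` for sensitivity analysis). The Center of
Mass CM = Σ r·q(r)/Σ q(r) is undefined — recorded as missing, not 0 —
when every q(r) is zero, because 0 is a meaningful interior value of the
statistic. For the width-3 zone, CM reduces to
(q(1) − q(−1)) / (q(−1) + q(0) + q(1)). The intratumoral density INT is
pooled: cells on tumor-class pixels / total tumor-class area (a
hexagon-mean variant exists; pooled is the default because the quantity
describes the whole compartment, not a sampling unit). Follicle area is
excluded from density denominators and cells inside follicle pixels are
dropped by default: follicles are segmented as a separate class precisely
to keep organized lymphoid aggregates out of microenvironment densities.

**Case QC.** Cases with total tumor-class area < 4.5 mm² fail QC; the
boundary is inclusive (exactly 4.5 mm² passes). Failing cases are computed
and flagged, never silently dropped.

## Cohort statistics

* Fisher's exact test (two-sided, hypergeometric-sum p, sample odds ratio)
  for categorical associations.
* Group comparisons of density indicators apply ln(x + 1) first (densities
  are left-skewed with exact zeros; the +1 offset is configurable), then
  one-way ANOVA with Bonferroni-adjusted pairwise Welch t-tests and a
  Kolmogorov–Smirnov normality note.
* Optimal survival cutoffs scan every midpoint between consecutive
  distinct indicator values whose split leaves both groups ≥ 10% of the
  cohort, minimizing the two-group log-rank p; ties resolve to the smaller
  cutoff. The returned p is the raw scan minimum — deliberately
  uncorrected, and therefore flagged `exploratory` in every output.
* Kaplan–Meier curves with t-month survival read off the right-continuous
  step function at exactly t (60 months for 5-year OS).
* Cox proportional hazards uses Efron tie handling (lifelines). Stepwise
  selection is forward entry by the best likelihood-ratio p < 0.05 with
  backward LR removal at p > 0.05 after each entry, iterated to stability.
  The null partial log-likelihood is computed in closed form at β = 0.
  Zero-variance covariates are excluded with a warning; fewer than 5
  events per candidate term triggers a warning.
* Leave-one-out cross-validation refits the model on every n−1 subset and
  evaluates the held-out linear predictors by Harrell's concordance index
  and an out-of-sample Breslow partial log-likelihood
  (Verweij–van Houwelingen construction). Note that Harrell's index counts
  tied predictions as 1/2, so a perfectly predictive *binary* covariate
  tops out below 1; only a continuous perfect predictor reaches 1.0.

## Scores

High CM strata for CD8 and CD20 (high = strictly greater than the cutoff;
a value exactly at the cutoff is low) and the pushing growth pattern each
contribute 1 favorable point. CD8–CD20 score = CD8 bin + CD20 bin ∈
{0,1,2}; IIS adds the growth bin, ∈ {0,1,2,3}. Missing inputs propagate to
missing scores. Cutoffs may be learned in-sample (as in clinical practice
with Cutoff Finder-style tools — optimistically biased, and labelled as
such in the output) or supplied externally.

## Synthetic data

The generator emulates the *structure* the pipeline assumes, not
histology: one star-convex tumor blob per slide with a radial boundary
r(θ) = R(1 + roughness), where the roughness is a random low-order Fourier
series — amplitude 0 gives a circular "pushing" margin, amplitude ≈ 0.12
with harmonics up to 12 a fingered "infiltrative" margin; stroma
elsewhere, an optional background frame, and disk-shaped lymphoid
follicles in the stroma. Marker cells follow an inhomogeneous Poisson
process with intensity λ(d) = a·exp(b·d) cells/mm², d the signed distance
(µm) to the ground-truth boundary, saturated at ±300 µm so densities
plateau away from the interface; b > 0 makes density gravitate toward the
tumor (CM > 0). Sampling is by thinning a homogeneous process at the peak
intensity; the signed distance comes from the Euclidean distance transform
of the rasterized ground-truth boundary, never from the hexagon ranks, so
the generator cannot share errors with the pipeline it tests.

Cohorts draw true binary strata from configured prevalences and survival
from an exponential model with hazard h₀·exp(Σ lnHR·(1 − bin)); censoring
is an independent Uniform(0, u) time with u solved analytically so the
expected censoring fraction hits the target. Defaults mirror the study
conditions the method was developed for: 87 patients, MSI prevalence
39/87, pushing-margin prevalence 49/87, unfavorable-stratum hazard ratios
1/0.31, 1/0.33 and 2.90, baseline hazard 0.001/month and 65% censoring.
Slide defaults are a 3.2 × 3.2 mm raster at 4 µm/px with a ~5.3 mm² tumor
(above the QC floor) and interface densities of order 40–400 cells/mm²
falling toward the tumor, matching the magnitudes reported for colorectal
microenvironments.

What the generator does **not** emulate: multi-blob and metastatic
topologies, necrosis inside the tumor, texture-driven segmentation errors,
marker-specific clustering (cells are Poisson given the intensity), and
correlations between indicators and clinical covariates beyond the three
configured strata. Passing tests therefore demonstrate correctness of the
computations and recoverability of configured effects — not clinical
validity on real slides.

## Problem sizes

Tests and the acceptance script run scaled-down experiments chosen as the
package's own verification sizes: rank-oracle checks on ~80-hexagon blob
fixtures (20 replicates), sign-recovery on 1.6 × 1.6 mm slides with ≥ 5000
cells (50 replicates), hazard-ratio recovery on 400-patient cohorts, null
calibration on 200 replicates of 100 patients, and Cox recovery on 100
replicates of 300 patients.

## Known limitations

* The TE definition ("mixed hexagons plus tumor touching stroma") is one
  reasonable reading of an area-fraction-change rule; sub-hexagon vector
  interface geometry is out of scope.
* The TE is treated as one global set; per-tumor-region components are not
  separated.
* In-sample cutoffs plus in-sample KM overstate significance; the outputs
  carry the exploratory flag but no correction.
* The hexagon side default (65 µm) is a documented choice, not a published
  constant; results at other scales require the override.
* No competing risks, time-varying covariates, or proportional-hazards
  diagnostics beyond warnings.
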