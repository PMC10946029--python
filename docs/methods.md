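# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic generator does and does
not emulate, and the numerical choices made where the design was open.

## Geometry conventions

Coordinates are 0-based pixel indices, x rightward, y downward; all
geometry is in pixel units on a 69×69-px stimulus patch whose centre is
(34, 34).  The figure side of a contour is a signed normal convention:
with `figure_side = +1` the figure lies to the left of the traversal
direction (for a rightward-travelling contour in screen coordinates,
"left" is decreasing y).  Mirroring a contour about its central tangent
flips the flag, so the physical figure side is preserved — matching the
contrast-inverted mirror stimuli of recorded experiments.

## Receptive field

The CRF is an axis-aligned 2-D Gaussian
`r(x,y) = baseline + amplitude·exp(−(x−cx)²/(2sx²) − (y−cy)²/(2sy²))`
fitted to grating-grid responses by bounded nonlinear least squares with
moment-based initialisation.  No rotation term is included: the extent
test stays closed-form and the axis-aligned model is the simplest
consistent with a 5×5 response grid.  The extent is the *open* 2-SD
ellipse (strict inequality).  A grid with equal responses everywhere is
unfittable and the neuron is excluded downstream; a negative fitted
baseline is clipped to zero.

## Contour features

**Closure** casts 100 rays from the CRF centre at equal angular
intervals.  A ray collides when its first intersection with the contour
polyline lies strictly inside the extent; tangential grazing counts, and
intersections within 1e-6 px of the ray origin are ignored (the origin
may lie on the contour).  Closure is the collided fraction.

**Curvature** fits a circle (algebraic Kåsa least squares, exact on
noiseless circles; collinear point sets fall back to a line fit with
zero curvature) to the gated contour inside square windows at scales
{1, 3/4, 2/4, 1/4, 1/10} of the patch, slid in both directions in 10-px
steps.  Windows holding fewer than 10 gated points are skipped; fits
with an RMS radial residual above the 80th percentile of the
(stimulus, neuron) pair's error distribution are discarded; at most 20
lowest-error fits survive.  Each fit contributes
`sign · (2/(1+e^(−a/r)) − 1)` with `a = 20` (a characteristic radius of
20 px at the 69-px scale; `scale_factor` adapts other patch sizes).
The sign is +1 when the circle centre lies on the figure side,
determined by a vote over locally adjacent contour segments (robust for
closed contours where a single chord degenerates).  The error cutoff is
per (stimulus, neuron) because the gated points depend on the CRF; an
externally pooled cutoff can be injected via `error_cutoff`.

**Symmetry** rasterises the contour points, blurs with a 2-px Gaussian,
and takes the greatest fold-overlap over 24 axes (7.5° apart) through
the stimulus centre.  The overlap is a *ratio* — the folded mass
`Σ min(map, mirrored map)` divided by the total mass — so the score does
not scale with contour length; a normalised-correlation variant is
available (`mode="dot"`).  Raw scores are min–max normalised across the
stimulus set.  Symmetry is global (no CRF gating).

**Orientation** takes all point pairs 5 px apart in arc length with both
points in the extent and averages their tilts axially: angles are
doubled, unit vectors summed, and the resultant angle halved, which is
well defined across the 0°/180° wrap.  The naive arithmetic mean is
available behind `naive=True` for strict replication.  A low resultant
length flags direction-balanced (degenerate) samples.

Whenever the gated contour is insufficient — too few points, no
surviving circle fits, no qualifying pairs — the feature is *missing*,
never a default value.

## Tuning

Tuning maps are histograms of mean spikes per feature bin (closure and
symmetry: 10 bins on [0,1]; curvature: 20 bins on [−1,1]; orientation:
18 bins of 10°; counts are unreported upstream, so these resolutions are
configuration defaults), normalised by the map maximum.  The curvature
map accumulates each stimulus's response-weighted local-curvature
histogram across stimuli and divides by the pooled counts — the weighted
mean spikes per curvature bin.

Fits use f(x) = a·exp(−(x−b)²/c²) with 0 ≤ a,b,c ≤ 1 (strength a/c) for
closure and symmetry, and f(θ) = a·cos(θ−c)+d with b fixed to 1 for
curvature (−1 ≤ c ≤ 1, a and d free, strength a) and orientation
(θ in radians, 0 ≤ a ≤ 1, 0 ≤ c ≤ π, 0 ≤ d ≤ 1).  With these
constraints the orientation peak θ = c always lies inside the domain;
the function is not 180°-periodic over it, so wrap-around maps (both
ends high) are outside the model class — a capacity limit of the printed
family, kept as is.  The curvature optimum is the in-range argmax of the
fitted function; the orientation optimum is reported modulo 180°.

The reported parameters come from bounded least squares polished from
the ten best starts of a deterministic dense grid (ties broken by lowest
rmse, then lowest a); missing bins are excluded from fit and rmse.

**Permutation significance.**  Tuning is significant when the original
fit error beats the bottom 1% of the fit errors of 1,000 shuffled maps.
Two design points matter:

* *What is shuffled.*  The default shuffles the occupied-bin values of
  the map, asking whether the map's arrangement is closer to the tuning
  family than chance arrangements of the same values.  Shuffling the
  stimulus–response assignment instead (available as
  `shuffle_unit="stimuli"`) makes the null maps concentrate toward
  flatness, which the offset-bearing cosine family fits essentially
  perfectly; the null errors are then systematically smaller than any
  real map's and the test has no power.  Empirically the default is
  well calibrated: 0.008 significance on 500 feature-blind Poisson
  neurons at the 1% criterion.
* *How the nulls are fitted.*  Refitting 1,000 maps per neuron with a
  multistart optimiser is unaffordable; the test instead uses a
  deterministic dense-grid fitter with closed-form amplitude, applied
  identically to the original and every shuffled map, so the comparison
  is fair by construction.  The polished parameters are only used for
  reporting, never inside the test.

Exclusions: neurons with any missing curvature or orientation value are
excluded from those features' analyses; closure retains neurons with
partial missingness; symmetry is never missing.

## Mutual information

Plug-in MI in bits on a joint histogram with equal-width bins over the
observed range of each axis and nbin = ⌈1 + log₂ n⌉ per axis (Sturges'
rule; the literal base-10 reading of the printed formula is available as
`rule="log10"` but yields implausibly few bins).  Curvature is
multi-valued per stimulus and is expanded by pairing every local
curvature with the stimulus's response (`curvature_mode="mean"`
collapses to per-stimulus means).  Neurons whose total analysed spike
count is below 15 are excluded (threshold 0 disables the exclusion;
membership changes but no retained neuron's MI value does).
Significance uses feature-shuffling permutation at p < 0.05 (1,000
permutations; the count is unreported upstream).  Per-neuron profiles
report the greatest and least MI as fractions of the four-MI sum,
tested against the even split 0.25 by sign-flip permutation (10,000
resamples) with Cliff's delta; tuned-versus-untuned comparisons use the
Wilcoxon rank-sum test with effect size r = |z|/√N.

## Population analysis

Responses are trial-averaged and row-normalised by each neuron's maximum
across stimuli; all-zero neurons are dropped.  Dissimilarity is the
Euclidean distance between normalised rows (correlation distance
optional).  The embedding is nonmetric MDS (SMACOF) minimising Kruskal's
Stress-1 over 20 random restarts.  Because Stress-1 is invariant under
rotation, the raw coordinate axes of a SMACOF solution are an arbitrary
direction pair; embeddings are therefore rotated to their canonical
principal-axis frame (axis 0 = direction of maximal variance,
deterministic per-axis signs), which makes repeated runs directly
comparable, and per-axis reflections are oriented so the regression
slope of interest is positive.  Axis structure is read out by
equal-count grouping (5 groups), 30-neuron moving windows with a
15-window centred moving average (the smoothing span is unreported
upstream and config-exposed; span 1 is the identity), windowed standard
deviations as dispersion bands, and per-neuron OLS regressions of the
number of significant features (primary axis) and NS preference
(secondary axis) on the axis coordinate.

## Synthetic generator

The generator emulates the statistical targets of the recorded study's
stimulus curation, not its manual procedure: 69-px patches whose contour
passes through the patch centre (a vertex is anchored exactly at the
centre — with a sub-pixel offset of the ray origin from the polyline,
closure of open curves quantises near 0.25/0.5 instead of varying
continuously), quasi-uniform feature marginals, pairwise feature
correlations |R| ≤ 0.1, and mirror augmentation.  Candidates come from
six parametric families — segments, circular arcs, centre-anchored
spirals (the only open family that can wind around the centre and reach
closure → 1), circle-plus-tail loops, sinusoid-perturbed open splines,
and fold-symmetric two-branch curves — each anchored at a random
fraction of its length so that endpoint anchoring produces the low
closure stratum.  A 1,500-candidate pool is evaluated under a central
reference CRF (SD 12 px, 2-SD extent radius 24 px ≈ a third of the
patch), then a greedy stratified selection flattens the four 10-bin
marginals and a local-search refinement enforces the correlation bound;
infeasible targets raise an error suggesting a larger pool.  Each
selected geometry contributes its mirror and both a natural-kind and a
silhouette-kind stimulus.

Model neurons are Poisson: expected rate = baseline + gain · K ·
(ns_gain for natural stimuli), where K combines per-feature kernels
drawn from the same families the analysis fits (Gaussian over closure
and symmetry; single-cycle cosine over curvature and orientation).
Multi-feature neurons combine kernels additively — multiplicative
mixing of several sharp kernels suppresses the per-feature marginal
tuning far below what recorded multi-tuned populations show.  Untuned
neurons have zero gain with a compensating baseline.  Defaults: 20
trials per stimulus, gain 10, baseline 1 spike, populations of 24
untuned + 24 single- + 24 multi-feature neurons sharing six CRFs
(shared CRFs keep the per-CRF feature tables cacheable).

What the generator does **not** emulate: photographic texture and
colour (natural-kind stimuli are silhouette geometry plus a scalar gain),
response adaptation and serial dependence, spike-sorting artefacts,
inter-neuron noise correlations, and eccentricity-dependent CRF scaling.
A green end-to-end test therefore establishes that the pipeline recovers
planted tuning under Poisson noise with realistic stimulus statistics —
not that it is robust to every property of recorded data.

## Numerical notes

* Circle-fit degeneracy: near-singular normal equations fall back to a
  PCA line fit (zero curvature, perpendicular RMS as the error).
* Ray–segment intersection treats |denominator| < 1e-12 as parallel;
  endpoint inclusion means tangential grazing counts as a collision.
* The equal-count axis grouping breaks ties by stable input order.
* Permutation p-values use the add-one convention
  (1 + #{null at least as extreme}) / (n_perm + 1); identical seeds give
  identical results everywhere, with per-stage seeds derived through
  `numpy.random.SeedSequence`.
* MDS recovery tests use a tight convergence tolerance (eps 1e-12);
  routine embeddings default to eps 1e-7, 300 iterations, 20 restarts.

## Known limitations

* The orientation cosine family cannot represent wrap-around peaks; the
  sensitivity of orientation tuning detection is accordingly lower for
  peaks near 0°/180°.
* The plug-in MI estimator is positively biased (~(nbin−1)²/(2n·ln 2));
  no bias correction is applied, matching the analysis being modelled.
* The bin-value permutation null treats occupied-bin values as
  exchangeable although their sampling variances differ with bin counts;
  measured calibration is conservative (0.008 at the 1% criterion).
* Silhouette rendering labels each pixel by its nearest contour segment,
  which approximates the figure/ground partition near high-curvature
  regions of self-approaching contours.
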