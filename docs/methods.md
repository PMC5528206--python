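# Methods

This note documents the models and procedures `nichediverge` implements, the
design choices behind its synthetic-data generator, the numerical details
that matter for reproducing results, and the limitations of what the test
suite demonstrates.

## The suitability model

The core model is a presence-only maximum-entropy (Gibbs) model. Given a
feature map f over grid cells, the probability mass on a cell is

    p(cell) = exp(w · f(cell)) / Σ_ref exp(w · f(·)),

where the reference set is a uniform background sample of valid cells united
with the presence cells. The weights maximize

    Σ_presences log p(cell) − λ Σ_j |w_j|.

**Features.** Linear and quadratic terms of each continuous layer,
standardized against the training background sample, plus an untouched 0/1
indicator per binary layer. Quadratic features make the model's canonical
response a Gaussian bell in each variable, matching the simulator's truth;
hinge, product and threshold features are deliberately out of scope. Because
standardization constants come from the background sample, the fitted
surface is invariant (to float precision) under affine rescaling of any
continuous input layer.

**Optimization.** The objective is concave. The L1 penalty is handled by the
positive/negative split w = a − b with a, b ≥ 0, giving a smooth
bound-constrained problem solved by L-BFGS-B (scaled by 1/n_presences). The
optimizer is restarted up to five times — a restart clears the Hessian
approximation, which reliably un-sticks the rare runs that stop on relative
objective reduction — and the elastic-net subgradient residual is then
required to be below 1e-3 (typically it is below 1e-6). The recorded
objective history is the exact quantity the optimizer maximizes, so it is
non-decreasing; it equals the penalized log-likelihood wherever
min(a, b) = 0, in particular at the solution. The default penalty is
λ = 0.1·√(n_features/n_presences).

**Surfaces.** The raw surface is exp(w·f) normalized to sum to one over all
valid cells. The logistic surface uses a cell-count calibration,
raw·N/(1 + raw·N) with N the number of valid cells, so a cell at uniform
density maps to 0.5. This constant is documented and bit-reproducible; it is
not the prevalence-based convention some other software uses, and absolute
logistic values are therefore not comparable across programs (cell
orderings, thresholds-by-rank, and sum-to-one overlaps are).

**Evaluation.** Replicated seeded 75/25 splits of the distinct presence
cells (25 replicates by default); AUC is the Mann–Whitney probability that a
test presence outscores a background cell, with half-credit for ties.
Jackknife contributions are leave-one-variable-out drops in test AUC on a
fixed split, clipped at zero and normalized to sum to 100; when no removal
hurts the model the contributions fall back to uniform and are flagged.
Model variable sets (climate / climate+trees / climate+shapefiles / trees)
are compared by one-way ANOVA on replicate test AUCs with Tukey HSD
post-hoc pairs (scipy / statsmodels).

## Overlap statistics

Schoener's D = 1 − ½Σ|p_X − p_Y| and the Hellinger-based
I = 1 − ½Σ(√p_X − √p_Y)², both on surfaces standardized to sum to one over a
shared mask. The ½ factors are part of the definitions; without them the
statistics would leave [0, 1]. I ≥ D pointwise. Comparing surfaces with
different masks is an error rather than a silent re-mask, because re-masking
changes the distributions being compared. Overlap is computed on the mean
replicate raw surface after standardization.

## Background-similarity test

The accessible area ("background") of a species is delineated by a
great-circle buffer around its occurrences (200 and 700 km defaults,
reflecting natal-dispersal evidence for the motivating system) or by the
minimum-training-presence mask of its fitted model. The null distribution
for a pair (focal species actual surface, other species' background) is
built by repeatedly (default 100) drawing as many random background cells as
the focal species has occurrences, fitting the same model to a seeded 75%
of them, and recording D and I against the focal surface. The verdict uses
the percentile interval of the null at level α (default 0.05): observed
actual-vs-actual overlap below the lower bound is divergence, above the
upper bound conservatism, otherwise the null is not rejected. Empirical
tail probabilities and a normal-approximation interval (for mean ± sd style
reporting) are emitted alongside.

## Multivariate (PC-axis) test

Environmental values are extracted at both species' occurrences and at
n = 1,000 (default) background points per species; a single PCA on the
correlation matrix of the pooled rows gives shared axes, so actual and
background means are comparable in one coordinate system. Axes explaining
at least 6% of variance are analyzed. On each axis, the observed mean
difference between species (d_actual) is compared with the range of
background mean differences over 25 replicates of 75% subsampling of the
background points: above the whole range is divergence, below it
conservatism, inside it inconclusive. Background points are drawn once per
analysis; replicate variation comes from the subsampling only. A constant
layer makes the correlation matrix undefined and is reported by name.

The range rule has a structural sensitivity worth knowing: d_actual carries
occurrence-sampling and landscape-realization noise that the subsample range
does not represent, so with few occurrences or a coarse landscape the test
over-calls divergence on axes that carry no signal. The simulation scale
used for the calibration checks (below) was chosen with this in mind.

## The synthetic landscape generator

The generator stands in for downloaded climate rasters and compiled
occurrence databases; its purpose is to produce studies whose truth is
known exactly, so that every verdict downstream can be scored.

**Environmental layers.** Each layer is a deterministic large-scale
component plus seeded white noise smoothed by a truncated Gaussian kernel
(radius three times the autocorrelation length), standardized to mean 0,
sd 1. Like real bioclimatic suites, most layers are collinear: they share a
deterministic latitudinal trend so that any two members of the suite
correlate at r ≈ 0.65 (below the conventional 0.7 screening threshold).
This is not cosmetic — correlation-matrix PCA has stable, meaningful axes
only when the correlation matrix is far from the identity; with mutually
independent layers the eigenvalues are nearly equal and the PC basis is an
arbitrary rotation, which smears any single-axis signal across all
components. Layers that carry planted niche structure (layer 1 by default)
instead get longitudinal deterministic structure and no shared trend, which
keeps a shift planted there statistically identifiable and, because
accessible areas are longitude bands, geometrically decoupled from the
collinear suite.

**Species.** Niche responses are Gaussian bells per layer
(exp(−Σ w_k(x_k−o_k)²/2b_k²), rescaled to max 1); the canonical virtual
species responds to a single dominant axis (layer 1) with breadth 0.7 sd,
the way real species tend to be limited by one or two variables while the
remaining layers are uninformative candidate covariates. Divergence
scenarios shift the two species' optima symmetrically ±1 breadth about the
layer mean (2 breadths apart in total); the symmetric split keeps both
species out of the rare tails of the environment distribution, where
selection-weighted sampling would otherwise concentrate occurrences into a
few landscape patches and generate spurious realized differences on other
axes. Conservatism scenarios use one identical niche for both species.

**Backgrounds and occurrences.** Accessible areas are two equal longitude
bands spanning the full latitude range, offset east–west so each shares
~70% of its area with the other (unions of circular regions and explicit
masks are also supported). Occurrences are drawn with probability
proportional to true suitability within the species' band, at most one per
cell (with redraws), jittered uniformly within the cell, and given breeding
dates and small coordinate uncertainties so they pass the cleaning filters.
Tree (biotic) layers are Gaussian-niche suitability surfaces of randomized
tree species on the same landscape; binary "range" layers are those
surfaces thresholded at 0.2.

**What the generator does not emulate.** Real spatial sampling bias,
observer effort gradients, temporal climate change, dispersal limitation
within the accessible area, interactions among species, and non-Gaussian
(e.g. skewed or bimodal) niche responses. Passing calibration tests on
these landscapes shows the procedures are internally coherent and recover
planted truths under favorable, known conditions — not that they are robust
to the pathologies of real occurrence data.

## Occurrence cleaning

Breeding-window filtering (inclusive month-day bounds, any year),
coordinate-uncertainty filtering (strictly below 5 km by default),
per-grid-cell deduplication (first record wins), and seeded greedy spacing
thinning (visit in random order, keep a record iff ≥ the minimum spacing
from everything already kept) — the only reproducible reading of "manual
thinning to uniform density". Records missing the metadata a filter needs
fail that filter. Every step logs in/removed/out counts, and the counts
reconcile exactly across a pipeline. Great-circle distances use the
haversine formula with Earth radius 6371.0088 km.

## Habitat importance values

For each tree species within a vegetation study: relative frequency (sites
with the species / total sites), relative abundance (individuals / total),
relative dominance (basal area / total), and their mean, the importance
value. Cross-study averages are unweighted; selection keeps species whose
average strictly exceeds 20%. Taxon exclusions (e.g. shrubs absent from
some studies) are caller-supplied.

## Pipeline

`run_pipeline` sequences simulate → clean → fit the four variable sets for
both species → ANOVA/Tukey comparison → overlap on the climate+trees
surfaces → background-similarity tests (two directions × 200 km / 700 km /
MTP backgrounds, D and I each: 12 comparisons) → multivariate test(s).
For the multivariate stage the default background source is the simulated
species' true accessible areas (`mv_background="true_range"`): in a
simulation the accessible area is known, and it is the correct availability
reference. The `"delineated"` mode instead runs one multivariate test per
buffer/MTP background, the only option with field data; at desk-scale
simulation sizes the delineated backgrounds either hug the
selection-weighted occurrences or cover the whole map, so their
availability reference is biased and conservatism scenarios can show
spurious multivariate divergence — a property of those background
delineations, not of the test logic. Every report embeds the resolved
configuration, its hash, seeds, provenance counts and per-stage timings,
and serializes to JSON.

## Problem sizes used in the checks

The calibration and acceptance checks run at deliberately chosen scales:
overlap and fit oracles on toy grids (20–48 cells); discrimination checks on
a 100×100 landscape with 100 occurrences; jackknife recovery on 60×60 with
200 occurrences (20 seeds); background-similarity error rates on 70×70
landscapes with 150 occurrences per species, 5-replicate mean surfaces and
50-replicate nulls (20 seeds each for conservatism and divergence);
multivariate axis recovery on 200×200 landscapes with 1,500 occurrences per
species, n_bg = 500 and 25 replicates (20 seeds). The multivariate scale is
the largest because the range rule needs occurrence-mean noise to be small
relative to background availability differences (see above). Library
defaults remain at the canonical study design (25 model replicates,
100-replicate nulls, n_bg = 1,000, 25 multivariate replicates, α = 0.05,
6% retention).

## Numerical choices and degenerate inputs

- Grid geometry: row 0 is the northernmost row; cell intervals are
  half-open, boundary points belong to the larger index; headers compare
  equal within 1e-9.
- ASCII serialization uses shortest-round-trip decimal tokens, so
  write→read is exact; masked cells are written as the literal nodata token.
- Percentile confidence bounds use linear interpolation.
- PCA eigenvalues are clipped at zero; loadings are unit eigenvectors with
  arbitrary sign.
- Constant layers: correlation screening reports them by name (NaN entries,
  no crash); PCA raises naming the layer.
- Degenerate fits: fewer than 5 distinct presence cells, identical presence
  features, or a failed subgradient condition raise typed errors; replicate
  background fits are retried up to 3 times with fresh draws and failures
  are counted in the result.
- ANOVA with zero within-group variance in all groups raises rather than
  returning an infinite F.

## Known limitations

- The logistic calibration constant differs from other maxent
  implementations (see above); only scale-free quantities are comparable.
- Percent contribution is defined via jackknife AUC drops; path-dependent
  gain-attribution schemes used elsewhere are not reproducible from first
  principles and are not implemented.
- The multivariate range rule is anti-conservative for small occurrence
  samples (documented above); the package reports the ingredients
  (d_actual, range, per-axis verdict) so users can judge margins.
- Buffer and MTP background delineations are meaningful only when the
  buffer radius is small relative to the study extent; at simulation scale
  the true-range mode is preferred and is the pipeline default.
- No reprojection, polygon handling, GeoTIFF/NetCDF support, or map
  rendering; rasters are ESRI ASCII grids in unprojected WGS84 degrees.
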