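# Methods

This note documents the models, estimators and design choices implemented in
`glomnet`, and what the synthetic-data generators do and do not emulate.

## Bipartite connection models

The granule-cell layer is abstracted as a bipartite graph: `n_gc` GC nodes
(default 3000) with exactly `dendrites_per_gc` edges each (default 4), and
`n_glom` glomerulus nodes (default 1000). GC IDs 1..n_gc encode parallel-fiber
depth order (lower = deeper = earlier born); glomerulus identity carries no
geometry. The random model places each GC's dendrites uniformly without
replacement, the only constraint being that a GC never contacts the same
glomerulus twice; glomerulus degrees are then Binomial(n_gc·4, 1/n_glom)-
distributed with mean 12. The model deliberately omits morphological and
geometric constraints (dendrite reach, soma positions): it isolates the
ID-structure of connectivity from anatomy.

### Rewiring

Preferential/avoidance topologies are produced by exactly `trials`
pick–evaluate–maybe-swap iterations. Each iteration draws two edges uniformly
from the global edge list. The pick is rejected — but still consumes a
trial, keeping trial counts comparable across runs and severities — when the
edges share a glomerulus, carry the same GC ID, touch a degree-1 glomerulus
(the score's denominator would vanish), or when the swap would duplicate an
existing GC–glomerulus contact. Otherwise the before/after scores S0 and S
(sums of mean absolute ID distances from each picked dendrite — or its
hypothetical replacement — to the other dendrites of the glomerulus) decide
execution under a
*strict* inequality; ties never execute. Swaps exchange the two GC IDs
between glomeruli, so both degree sequences are conserved exactly.

Severity presets (mild/moderate/severe = 2500/5000/7500 preferential,
1000/4000/10000 avoidance trials) and the 50-configuration ensemble default
mirror the study conditions; each rewired configuration derives one-to-one
from a random configuration. All randomness flows from a single integer seed
per configuration (numpy `default_rng`); identical seeds give bit-identical
networks.

### Diagnostics

Proximity index per glomerulus: PI = (N(N−1)/2) / Σ_{i<j}|x_j−x_i|, i.e. the
inverse mean pairwise ID distance, averaged over glomeruli with ≥2 dendrites
(degree-<2 glomeruli are excluded, not zero-filled). Label coverage: the
fraction of glomeruli containing ≥1 dendrite from an inclusive ID window.

## Virtual labeling and intensity model

Injection-age presets label 30% ID windows (P7 = 1–900 shifting to
P13 = 2101–3000). For realistic pairs the doubly labeled block defaults to
the *natural intersection* of the two windows, which reproduces the printed
windows exactly; an explicit overlap fraction instead places the block
straddling the junction of the two windows, split evenly, with window widths
preserved at 30% per fluorophore. Doubly labeled GCs count toward both
channels.

Channel intensities per glomerulus are Σ_n lognormal(mean 1.0, sd 0.6) + one
lognormal(mean 0.3, sd 0.1) noise draw. The "mean/sd" pairs are interpreted
as natural-scale moments and moment-matched to the underlying normal
(σ_log² = ln(1+(sd/mean)²)); degenerate parameters (sd = 0) collapse to
constants so closed-form checks are possible. The noise draw keeps both
channels strictly positive, so ratios are always finite.

## Ratio-dispersion statistic

σ̂ is the maximum-likelihood lognormal shape: the population (ddof = 0)
standard deviation of log ratios (equivalently `scipy.stats.lognorm.fit`
with `floc=0`; the test suite cross-checks the two routes). Shuffled nulls
permute the GFP column against the tdT column *within* a provenance group
(`image_id`/`config_id`), never across; shuffles are plain permutations, not
derangements. Model-style analyses default to 20 shuffles per configuration,
experimental-style tables to 50. Δσ̂ averages (σ̂_shuffle − σ̂_data) over
shuffles and configurations; its sign tracks the within-glomerulus channel
covariance.

The first-order (delta-method) ratio-variance approximation is provided as
an analytic diagnostic. Its relative error against simulated lognormal
channels grows like ~3·CV² (the exact lognormal-ratio variance is
e^{s²}(e^{s²}−1) versus s² to first order), i.e. ≈9% at CV 0.17 and ≈19% at
CV 0.3 for uncorrelated channels; positive correlation cancels part of the
error. The unit tests assert the graded envelope max(0.10, 4·CV²·(1−ρ)); the
formula's value is its *sign* logic — negative covariance broadens, positive
narrows — which is exact.

## Spatial statistics on the soma lattice

Labeled somas are events on the irregular lattice of all somas; the analysis
window is the convex hull of the lattice and the null is Bernoulli selection
on the lattice (not free-space CSR). Ĝ and F̂ are empirical CDFs of
nearest-neighbour distances (inclusive ≤ on the grid); F̂ reference points
are a binomial process in the hull, defaulting to as many points as events.
K̂ follows the plain double-sum estimator with *strict* inequality and no
edge correction: it is biased low at radii comparable to the hull scale and
is meant for comparison against null configurations estimated identically,
not against πr². Envelopes are pointwise Monte-Carlo quantile bands (default
50 simulations, 95%).

The clustering permutation picks one selected and one unselected soma per
trial, compares the selected:unselected ratio within 8 μm circles (both
picked somas excluded from the counts; a zero denominator counts as +∞,
which favors swaps toward saturated neighbourhoods), and exchanges labels
when the selected soma sits in the poorer neighbourhood. 20,000 trials
bring executed swaps to a plateau on a 3000-point lattice. The selected
count is invariant.

The Bernoulli selection intentionally leaves the selected *count* random
(binomial); an exact-count variant without replacement is available by
sampling the mask externally, but the Bernoulli form is the default contract.

## MF-terminal categorization

GC depth groups default to D = 1–1000, M = 1001–2000, S = 2001–3000.
Dominancy ranks glomeruli by each group's dendrite *fraction* (descending,
stable) and takes the top floor(33%) plus cutoff ties, independently per
group — populations may overlap or leave glomeruli unassigned. Order
categorization maps each glomerulus to the permutation of (D, M, S) sorted
by descending count, ties broken by the fixed order D, M, S. Summaries
average per-population labeled-dendrite counts over configurations.

## Image pipeline

Preprocessing: Wiener filter (5 px window) then CLAHE (clip 0.01); constant
images pass through unchanged (zeroed) since there is no structure to
equalize. Segmentation: (1) the two structural channels are summed and
thresholded (config scalar, or Otsu by default) to delimit glomerulus
cluster areas; (2) central voids are detected on the Gaussian-smoothed
(σ = 2 px) membrane channel by an H-minima transform (depth 0.15 of the
intensity range) with marker size filtering; (3) a marker-based watershed
constrained to the cluster areas assigns pixels to glomeruli. Regions below
30 px or listed in a plain-text exclusion file are dropped and reported;
regions are never added manually. Pixel grid is 0-based row-major; areas in
pixels. H-minima depth, window sizes and size bounds were calibrated once on
the synthetic generator's default geometry and are plain config parameters.

Per-region channel means are normalized by the per-image median over
regions, so tables are scale-free and schema-compatible with the simulated
intensity tables. The (I − IB)/IW normalization and the Gaussian profile
fit (amplitude, center, width, offset via least squares) are direct
implementations.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *geometry and statistics* the estimators rely
on: hard-core soma lattices at the native field scale (211.7 μm, 3000
somas, 2.5 μm minimum spacing — a sequential-adsorption stand-in for soma
exclusion in a 2-D optical section), labeled subsets with tunable seeded
clustering, bivariate-lognormal intensity tables with exact log-scale
correlation ρ, and glomerulus images as annuli with dark voids plus terminal
blobs (radius 8–12 px in a 256 px field, 30 per image, light blur, additive
Gaussian noise sd 0.05). They do **not** emulate optical point-spread
functions, depth attenuation, fluorophore maturation or segmentation-
confounding anatomy (touching glomeruli, vasculature); passing the
segmentation round trip therefore shows the pipeline is correct and
deterministic, not that it would reach the same recall on real tissue, where
thresholds are tuned per image.

## Problem sizes

Default analyses use the native model scale (3000/1000/4). Ensemble sizes in
the test suite are 50 configurations for degree/coverage properties, 20 for
proximity-index ordering, and 10 configurations × 20 shuffles for the Δσ̂
sign pattern; spatial envelopes use an 800-point lattice for the unit tests
and the native 3000-point lattice in the examples. These sizes give
Monte-Carlo errors comfortably below the effect sizes under test.

## Known limitations

- The rewiring trial counter includes rejected degenerate picks; if a
  different accounting were intended, severity presets shift slightly along
  the trial axis (the ordering and monotonicity properties are unaffected).
- No edge-corrected K variant; comparisons are only valid within a fixed
  lattice/boundary.
- The delta-method ratio-variance diagnostic is first-order accurate only
  (see above).
- The dominancy cutoff (top 33%) includes ties, so population sizes can
  slightly exceed floor(0.33·n_glom).
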