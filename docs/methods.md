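# Methods

This note records the models, conventions and numerical choices behind
`nucmorph`, in the spirit of a statistical software methods appendix:
what each stage assumes, which knobs matter, and what the synthetic
validation does and does not establish.

## Measurement conventions

Coordinates are 0-based image coordinates: x rightward (columns), y
downward (rows). Nuclear orientation is the angle of the ellipse-fit
major axis (from second central moments of the pixel set), measured from
the +x axis in that frame, on [0°, 180°) — nuclei are axial objects, so
angles are taken modulo 180°. Boundaries are traced at the 0.5 iso-level
of the padded component image and stored counterclockwise; they are
shifted to local coordinates before shape analysis so descriptors are
exactly translation-invariant.

Connected components use 8-connectivity. Components below `min_area`
(default 15 px² at ×20 magnification) are discarded as segmentation
specks. Probability maps are thresholded at `t = 0.5` by default with the
≥ convention. Magnification rescaling interpolates intensities
(bi-linear, anti-aliased when downscaling) and uses nearest-neighbor for
label masks so no interpolated labels appear.

Feature-block aggregation uses the population standard deviation
(ddof = 0), so a single observation has sd 0 rather than NaN; the
Bhattacharyya distance, an inferential quantity, uses sample variances
(ddof = 1). Aggregate min/max ratios are taken on magnitudes and defined
as 1 when all magnitudes vanish (relevant for near-zero descriptors such
as high-order Fourier coefficients of a circle).

## Feature families

**Global graph (51).** Voronoi cells are made finite by mirroring the
point set across the four sides of the field rectangle before
tessellating, then clipping each original point's cell to the rectangle —
boundary nuclei keep (truncated) cells instead of being dropped. Chord
lengths are all vertex-to-vertex distances of the cell polygon (edges
plus diagonals). Delaunay statistics cover triangle areas and unique edge
lengths; the MST is computed on the complete Euclidean distance matrix.
Density features use neighbor counts within radii {10, 20, 30, 40, 50} px,
distances to the 3rd/5th/7th nearest neighbor, and counts in 100 px
square windows slid at stride 50. Radii and k values are fixed in code;
together the groups partition 12 + 8 + 4 + 27 = 51.

**Cell cluster graph (25).** The probabilistic decaying-edge construction
is made deterministic: edge iff `d(u,v) ≤ r^(−1/α)`, defaults α = 0.5,
r = 0.2 (threshold 25 px at ×20), which makes every downstream statistic
reproducible. Path statistics (eccentricity, diameter, radius, average
shortest path) are computed per connected component with ≥ 2 nodes and
size-weight-averaged; isolated nodes are excluded from them but counted
in the percentage statistics. The per-cluster edge density (edges over
possible pairs, averaged across components) follows the local-cluster
reading of graph density. Robust variants: the 90th percentile of node
eccentricities, the 90th percentile of all pairwise path lengths
("diameter 90%") and the 10th percentile of eccentricities
("radius 90%"). Edge-length skewness is the adjusted Fisher–Pearson form
and kurtosis is excess kurtosis, both 0 with fewer than 3 (resp. 4)
edges; with no edges all edge-length statistics are 0 by convention.

**Cell orientation entropy (39).** Orientations are quantized into
B = 10 bins of 18° (configurable). For each nucleus with at least two
CCG neighbors, all unordered pairs in its *closed* neighborhood (the
nucleus plus its neighbors) increment a B×B co-occurrence matrix, which
is symmetrized and normalized. Thirteen second-order statistics are
computed per matrix and aggregated across nuclei by {mean, sd, range}.
The information measure of correlation 1 is reported as
`(HXY1 − HXY)/max(HX, HY)` — the negation of the classical signed form —
so that it is nonnegative and *increases* as neighboring orientations
decouple; this matches the empirical direction in which loss of nuclear
polarity drives the statistic and keeps "higher = more disordered"
consistent across the entropy-family features. Logs are base 2 with
0·log 0 ≡ 0; degenerate marginals (all orientations in one bin) yield 0
for correlation-type statistics. A field in which no nucleus has two
neighbors produces an all-zero block with a warning.

**Shape (100).** Boundaries are resampled to 128 equal-arc-length points
before the radial-distance sequence is analyzed (smoothness = mean
absolute deviation of each radial distance from its neighbors' mean,
normalized by the mean radius; Fourier descriptors = magnitudes of
coefficients 1–10 of the radial sequence normalized by the DC term).
The minimum enclosing circle comes from computational-geometry routines
(`shapely.minimum_bounding_radius`); Hu moments and eccentricity from
normalized central moments of the pixel set; the boundary fractal
dimension from box counting at 5 dyadic scales. 25 descriptors ×
{mean, sd, median, min/max ratio} = 100.

**Haralick texture (26).** Per-nucleus GLCMs quantize the within-mask
gray levels to 64 (per-nucleus min–max), accumulate distance-1
co-occurrences over 4 directions with a sentinel level masking
non-nucleus pixels, symmetrize and normalize; nuclei under 16 px are
skipped. The same 13 statistics as the orientation family, aggregated by
{mean, sd}.

## Ranking, classification, separability

The correlation ranker is the absolute point-biserial correlation with
the 0/1 label (constant features rank last). The rank-sum ranker uses an
exact null distribution of the rank sum when both classes have ≤ 10
samples (a cached convolution for untied data, direct enumeration over
C(n+m, n) midrank assignments otherwise) and a continuity-corrected,
tie-corrected normal approximation above that; all pooled values equal
gives p = 1. mRMR discretizes each feature to 3 states at z = ±1 within
the provided data, measures relevance/redundancy as mutual information in
bits from joint frequency tables, and greedily maximizes
relevance − mean-redundancy (mid) or relevance / mean-redundancy (miq,
denominator floored at 1e-6). All rankers break ties lexicographically by
feature name, so results are bit-reproducible.

Classifiers: LDA (pooled covariance); QDA with a diagonal ridge
λ·trace(S)/d (λ = 1e-3) added to each class covariance, because the
protocol trains on as few as 4 samples per class where raw covariances
are singular; and a linear SVM with C = 1 on features standardized by
training-fold mean/sd. The linear kernel and fixed margin are the minimal
assumptions for so small a training set. AUC is the Mann–Whitney midrank
statistic (ties count ½), computed for the higher-risk class as positive.

Each CV round draws an equal number of training patients per class
without replacement (the remainder tests), ranks **within the training
fold only**, keeps the top 3 features to limit overfitting, and records
the test AUC and the mean Gaussian Bhattacharyya distance of the three
selected features between the test-split classes. The Gaussian closed
form is used deliberately: test splits contain as few as 3 patients per
class, where histogram estimates of the Bhattacharyya coefficient are
meaningless. Variances are floored at 1e-12 so degenerate splits stay
finite.

## Consensus clustering

Features are z-scored (constant columns dropped with a warning) and
projected onto the top two principal components, with component signs
fixed by the largest-magnitude loading. Each of 50 runs samples
⌈0.8·n⌉ patients without replacement and cuts an average-linkage
dendrogram at k = 2; the consensus entry for a pair is its co-cluster
fraction among co-sampled runs (never co-sampled → 0 with a warning).
The final partition cuts an average-linkage tree of (1 − consensus) at
k = 2, and cluster 1 is deterministically the group with the higher mean
first-component score.

The pairwise distance on the 2-D score profiles is Euclidean by default.
A centered Pearson-correlation distance between 2-vectors collapses to
the two values {0, 2} and carries no usable geometry, so the correlation
metric — meaningful for longer profiles such as the six-feature image
signature — is available behind the `distance="pearson"` flag rather
than as the default. Linkage is average throughout. Clustering can also
run directly on the named six-feature signature (orientation-entropy mean
information measure 1; CCG edge-length skewness and average component
size; Voronoi chord min/max ratio, polygon-area sd, polygon-area min/max
ratio) via `ConsensusCluster(use_pca=False)`.

## Synthetic tissue generator

The generator emulates the aspects of tissue morphology the features
measure, not the appearance of stained tissue. Nuclei are filled
ellipses: area lognormal about `mean_area` (log-sd 0.2 by default),
aspect ratio uniform on [1.6, 2.8] so orientation is always well defined.
Placement blends a hard-core process (candidates rejected within
`hardcore_radius` of an accepted nucleus) with a Thomas-like
parent–offspring process: with probability `clustering` a candidate is
drawn around one of ~n/12 parents with dispersion 6% of the field, else
uniformly. Placement retries are bounded (300·n); the achieved count is
reported, and a field too small to accept any nucleus raises an explicit
placement error.

Orientations are wrapped-normal about a per-image global axis. The
dispersion is parameterized through the mean resultant length of the
doubled angles, `R = 1 − 0.98·orientation_disorder`, so the population
circular variance rises linearly over the knob's whole range rather than
saturating near uniformity by mid-range — this keeps high-disorder
levels statistically distinguishable. `orientation_disorder = 0` sets
every axis exactly to the global axis. Intensities are a bright
background (230), per-nucleus base levels uniform on [80, 160], and
pixelwise Gaussian noise with sd 12·`texture_heterogeneity`, clipped to
[0, 255].

What passing tests on these cohorts shows: the pipeline's statistics
respond monotonically and reproducibly to controlled changes in
orientation disorder, spatial clustering and planted feature shifts, and
the protocol is correctly calibrated under the null. What they do not
show: anything about staining variation, segmentation error, nuclear
pleomorphism beyond ellipses, or the effect sizes present in real
cohorts — real slides are not ellipse fields, and no claim about
patient-level discrimination transfers from the synthetic setting.

## Problem sizes and determinism

Default validation sizes are desk-scale by design: fields of 120–250
nuclei at 500–600 px, cohorts of tens of patients, 100 CV rounds, 1000
null replicates, 5 × 10 seeded generations for monotonicity sweeps. The
orientation-disorder sweep uses a denser field (250 nuclei / 550 px)
because co-occurrence entropy needs neighborhoods of more than a few
nuclei to have headroom at high dispersion; sweeps use common random
numbers (the same seeds at every level) so level contrasts are not
swamped by between-field variance. Every stochastic component takes an
explicit seed; cohort and pipeline stages derive per-item seeds from a
single master seed via `numpy.random.SeedSequence`, so stages can be
rerun in isolation and end-to-end outputs are byte-stable.

## Known limitations

* The 51/100/39/25/26 rosters match the published family cardinalities
  and every individually named feature, but name-level identity with any
  external implementation of the same families cannot be guaranteed.
* The CCG is deterministic by construction here; stochastic realizations
  of the decaying-edge rule are out of scope.
* mRMR's 3-state discretization loses power at very small training
  folds (≤ 7 per class); the correlation and rank-sum rankers are more
  reliable there.
* Histogram-based Bhattacharyya estimation is not implemented; the
  Gaussian form is exact only for Gaussian class-conditionals.
* The consensus matrix treats never-co-sampled pairs as 0, which at very
  low resampling rates would bias consensus downward; at the default 0.8
  rate over 50 runs every pair is co-sampled with overwhelming
  probability.
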