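# Methods

This note documents the models, numerical conventions and open design
choices behind `potpheno`, in the order the pipeline runs them.

## Segmentation

Images are assumed to be front-view photographs of a single potted
plant against a near-white, uniformly lit background. RGB is converted
to HSB by the standard hexcone model (H in degrees, S and B in
percent; achromatic pixels get S = 0 and H = 0 by convention). The
inverse transform recovers 8-bit RGB within ±1 level, which bounds the
numerical error of any colour-space round trip.

The threshold is the classic triangle method on a 256-bin histogram of
one channel. The peak is the max-count bin; the tail is the farthest
nonzero bin on the side with the longer peak-to-extreme span; the
threshold maximizes the perpendicular distance between the histogram
profile and the peak–tail line, with ties broken toward the tail. A
histogram with a single occupied bin defines no separation: the
threshold degenerates to that bin and segmentation reports failure.

Which HSB channel the original semi-manual workflow thresholded is not
documented anywhere we know of; brightness is the default here because
a white background separates best in B, and saturation is exposed as a
config switch for glossy or tinted backgrounds. Pixels at or below the
threshold bin (the darker side) are plant; connected components
smaller than `min_object_px` (default 64 px, 8-connectivity) are
removed, automating the manual touch-up step. A pot may hold more than
one seedling; the mask keeps the union of surviving components by
default (`largest_only` switches this off). A configurable bottom
margin is excluded because the calibration ruler is dark and would
otherwise survive thresholding.

## Morphometrics

All measurements follow the ImageJ-family conventions that produced
the numbers this kind of screen is usually compared against:

- **Pixel model.** The convex hull is taken over the outer corners of
  foreground pixels, so a w×h rectangle measures exactly w·h px² and
  hull area is an upper bound on pixel area by construction.
- **Feret / MinFeret.** Maximum caliper via the rotating-calipers
  antipodal scan over hull vertices (checked in the tests against the
  O(n²) pairwise maximum); minimum caliper as the smallest projection
  span perpendicular to a hull edge.
- **Ellipse.** The fitted ellipse keeps the region's area and the
  eigen-ratio of its central second moments (with the 1/12 per-pixel
  variance term, which also regularizes degenerate one-pixel-wide
  regions). Aspect ratio is major/minor; roundness is
  4·area/(π·major²) and may exceed 1 by a small pixelation slack.
- **Perimeter.** Moore-neighbour boundary tracing of each filled
  component (outer boundaries only; interior holes are ignored), with
  chain steps weighted 0.948 (axial) and 1.340 (diagonal) — the Kulpa
  corner-corrected weights. The naive (1, √2) weights are available
  via `ChainCodeWeights.NAIVE` but overestimate smooth outlines by the
  classic ~5%, which would put a digitized disc outside the package's
  own 3% accuracy target; the corrected weights keep it within ~1%.
  An isolated pixel contributes the constant 4 px (its crack outline).
- **Colour traits.** The hue band counted as green (60–180°, S ≥ 15%)
  and the saturation-area cutoff (S ≥ 25%) are explicit configuration:
  no published defaults exist for them, so they are exposed rather
  than hidden. The red/green/blue indices are the normalized mean
  channel fractions (they sum to 1). Integrated density is plant pixel
  count × mean brightness; a grey-mean variant is switchable, and the
  choice is recorded in output metadata.

## Trial model and screening statistics

The design is a nested randomized block: two salinity environments,
replicates nested within environment, several plants (samples) per
plot. The analysis model is fixed-effects,

    y = μ + stress + rep(stress) + genotype + genotype×stress + ε,

run per trait on log₁₀(x+1)-transformed values (the +1 offset keeps
near-zero ratio traits defined; base 10 for interpretability). Stress
is tested against the replicate-within-stress mean square (df 1 and
e(r−1)), genotype and G×S against the residual. By default samples are
averaged to plot means first, since the replication unit of the
published CV values is not documented; a sample-level variant pools
the within-plot stratum into the residual. CV% is
100·√MS_residual / grand mean of the transformed data. Zero-variance
degenerate inputs report p = 1 with a warning rather than failing.

BLUEs are least-squares genotype means adjusted for replicate blocks,
fitted per environment; on a balanced design they equal the
genotype×environment cell means, an identity the tests assert rather
than assume. No REML/BLUP machinery is used: with a balanced
single-location trial, fixed-effects least squares is exact and
simpler to audit.

The stress tolerance index is the Fernandez form,
STI = (Y_normal·Y_saline)/mean(Y_normal)², with the unstressed
environment as the "potential" denominator; it is invariant to
rescaling a trait in both environments. Relative decrease and increase
are (normal−saline)/normal and (saline−normal)/normal; the scale
(percent vs proportion) is always explicit, never inferred — pigment
tables conventionally print percent while ion comparisons print
proportions.

## Multivariate stage

PCA is an eigendecomposition of the correlation matrix (total variance
= number of variables). Sign indeterminacy is resolved by making the
largest-magnitude loading of each component positive, so the
biplot-quadrant labels — (+,+)→1, (−,+)→2, (−,−)→3, (+,−)→4 on the
(PC1, PC2) score signs — are reproducible across platforms. Factor
analysis uses principal-component extraction truncated to `n_factors`,
with communality as the row sum of squared loadings and per-factor
percent variance as column sum / number of variables; varimax is
off by default (published loading tables of this kind often come from
unrotated, tool-rescaled output) and, when on, preserves
communalities to 1e-8. Correlations are plain Pearson r with two-sided
t-tests and no multiple-testing correction: at n = 6 genotypes the r
values carry the information, and that choice is documented rather
than silently "improved".

## Synthetic generators

The renderer draws a fan of flat-capped capsules (tillers) from a base
point, rasterizes by pixel-center containment, colours foreground
pixels with seeded hue/saturation/brightness jitter around a green
band, and places a dark ruler bar in a reserved bottom margin. Ground
truth (hull area, Feret widths, bounding box, outline perimeter) is
computed from the generating vector geometry, never from pixels, so a
disagreement with the measurement code is attributable to pixelation
or to the code under test — not to the fixture. Geometry is
deterministic given the spec; the seed only moves colour jitter, and
identical seeds reproduce images bitwise.

The trial simulator emits the balanced long-format table
(6 genotypes × 2 environments × 3 replicates × 3 samples = 108 rows
per trait by default). Default effects reproduce the structure such a
pot screen shows: a strong stress depression (~30–45% of the mean) on
the 13 geometric traits, no genotype or G×S effects, with Gaussian
block (3%) and residual (8%) noise relative to each trait's mean.
Noise SDs may also be given on the absolute scale. Gaussian additive
noise is an assumption — the screen this emulates published no
distributional statement — and it is the simplest model consistent
with an ANOVA-based analysis. Because six traits are simulated as true
nulls, the α = 0.05 filter is expected to admit a false positive in
roughly a quarter of runs; integration tests therefore assert that all
designed-significant traits are recovered and that at most the
binomially plausible number of nulls slip through, rather than exact
set equality at one lucky seed.

The physiology generator assigns each genotype a tolerance class and
derives saline values from class parameters (chlorophyll/carotenoid
decline %, proline surge %, K⁺/Na⁺ shift: tolerant keeps the ratio
above 2, moderate near 1, sensitive collapses below 0.5). With zero
noise the class parameters are reproduced exactly, which the trivial
oracles in the tests exploit.

What the generators do **not** emulate: leaf curvature and occlusion,
soil/pot texture, specular highlights, camera noise, non-Gaussian or
heteroscedastic trial errors, and genotype-specific phenotypes.
Passing tests therefore demonstrate correctness of the measurement and
statistics chain under controlled conditions, not robustness to field
imagery.

## Problem sizes and runtime choices

Monte-Carlo calibrations (type-I rate, power) use 1,000 replicates of
the single-trait 108-sample design; the caliper and threshold oracle
sweeps use 500 random blobs and 1,000 random histograms. These sizes
give binomial standard errors well inside the asserted bands while the
whole suite stays in the low tens of seconds.

## Known limitations

- The triangle threshold assumes a dominant background mode; scenes
  without a clear peak-tail structure degrade gracefully but are not
  the target domain.
- The perimeter estimator is calibrated for smooth outlines; highly
  fractal masks will still be length-biased.
- `blue_estimate` requires a complete balanced table and refuses
  anything else; unbalanced or multi-location data need a mixed-model
  tool, which is out of scope.
- The PCA variance split of a published screen can only be compared
  softly when the exact variable set of the original ordination (e.g.
  an added selection-index column) is unknown.
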