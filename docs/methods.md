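# Methods

This note documents the models, numerical choices, and limitations behind
`eyemorph`. It covers what each stage assumes, which parameters matter and
why their defaults are what they are, and what the synthetic-data generator
does and does not emulate.

## Coordinate and unit conventions

Cast coordinates and outlines are flattened-cast plane positions in mm, with
y increasing dorsally (an arbitrary but documented convention). Facet
diameters are reported in μm (mm × 1000). Angles are degrees throughout,
including curvature (degrees of visual field per mm of eye surface).

## Facet geometry

**Neighbor graph.** The physical adjacency of ommatidia in a near-hexagonal
packing is recovered by Delaunay triangulation of the center points. Delaunay
also produces spurious edges: long chords along the outline's concavities and
bridges across cracks or gaps in the cast. These are pruned by edge length.
The default rule is *local*: an edge is removed when longer than 1.5× the
smaller of its two endpoints' median incident edge lengths. A single global
threshold (1.5× the global median, available as `prune_mode="global"`) fails
on real eyes: facet diameters span roughly 14–50 μm around a ~29 μm median,
so the genuinely enlarged acute-zone facets sit beyond 1.5× the global median
spacing and a global cut severs the very region of interest. The local rule
passes the same degeneracy checks (uniform lattices untouched; the √3·s and
2·s diagonals across a missing-facet hole are removed; hull-spanning spurs
are removed) while tolerating smooth diameter gradients. The factor 1.5 sits
between the nearest-neighbor distance (1×) and the second-neighbor distance
(√3 ≈ 1.73×) of a hexagonal lattice; anything in ~[1.3, 1.6] behaves the
same.

**Diameters.** Facet diameter = mean retained-edge length at the facet, in
μm. This equates center-to-center spacing with diameter, which is exact for
gap-free hexagonal tiling and is the standard reading of diameter estimation
from neighbor distances. Facets with no retained edge are isolated and carry
a missing value. Boundary facets (convex-hull vertices and facets that lost
an edge to pruning) have truncated neighborhoods that bias their mean edge
length; they are flagged, kept in counts and densities, but excluded from the
smallest/average/largest diameter summaries.

**Surface area.** Shoelace formula over the traced outline polygon, absolute
value so vertex orientation is irrelevant. The cast is treated as flat;
cutting and flattening distortion of the real cornea is not modeled.

**Histogram.** Relative frequencies in 2 μm bins aligned at even μm
(configurable); matches the granularity at which diameter distributions are
conventionally reported.

**Hotspot map.** One circle per facet colored by a fixed 9-anchor viridis
ramp from the minimum to the maximum diameter, gray for missing, with a
legend and 0.5 mm scale bar, written as plain deterministic SVG text. When
the diameter span is below 1e-9 relative the field is treated as uniform
(single mid-ramp color) rather than amplifying float noise across the ramp.
The acute zone is localized as the centroid of the top-decile facets.

## Optics

ΔΦ_G = √(23818/n) degrees assumes the eye surveys a hemispheric visual
field; the constant is used exactly as conventionally printed, not recomputed
from solid-angle first principles, so count↔angle round trips are exact.
The local estimate ΔΦ = D/(b/a) divides the mean local facet diameter
(μm → mm) by the local radius-of-curvature proxy b/a, where b mm of eye
surface subtends a degrees. The module accepts either an already-averaged D
or five raw diameters to average. Acuity = 2ΔΦ by definition here; smaller
ΔΦ is reported as better acuity. No diffraction limit, eye parameter, or
sensitivity equation is computed.

## Allometry

Ordinary least squares throughout (the analyses this package reproduces used
standard linear regression, not reduced major axis). Log-log fits use base
10 — the base shifts the intercept only, never the exponent. The isometry
reference is 1.0 because the built-in comparisons are linear-dimension vs
linear-dimension; for mass-based predictors pass `isometry_ref=1/3`.
Classification is a two-sided t-test of the slope against the reference at
α = 0.05. Slope comparison is the full-vs-reduced RSS F-test on the
group×predictor interaction (df = n_total − 4); intercept comparison is the
ANCOVA group-offset F-test under a common slope (df = n_total − 3), and is
only meaningful when the slope test does not reject. Exactly collinear
degenerate fits clamp F at 0 rather than returning small negative values
from floating-point cancellation.

## Group statistics

Normality passes only when Shapiro-Wilk (p ≥ α) *and* Anderson-Darling
(statistic below the α critical value) pass in every group; variance
homogeneity is the variance-ratio F-test, pairwise for more than two groups.
Two groups: pooled t when variances are homogeneous, Welch otherwise (the
dispatch the F-test gate implies). Three or more: one-way ANOVA when all
gates pass, else Kruskal-Wallis. The default post hoc after ANOVA is
pairwise t on the pooled mean-square error with Bonferroni adjustment over
all pairs (the procedure behind the "Bonferroni MCT" of common statistics
packages); Tukey HSD is available on request; after Kruskal-Wallis, Dunn's
test with average-rank tie correction and Bonferroni family adjustment
(two-sided). For k = 2 groups Dunn's z reduces to the asymptotic
Mann-Whitney z, which the tests exploit as an independent cross-check.

## Synthetic eye casts

The generator emulates what digitized casts look like statistically: a
hexagonal facet lattice, positional jitter from hand-picking centers, an
oval outline, and a dorsofrontal hotspot of enlarged facets.

The hotspot is a Gaussian-radial spacing multiplier
g(p) = 1 + (A−1)·exp(−|p−c|²/2σ²). A lattice with locally prescribed
spacing g has no exact flat embedding (the prescribed metric has non-zero
Gaussian curvature), so the generator uses an equal-area radial warp: the
reference radius r maps to R with r(R)² = 2∫₀ᴿ u/g(u)² du (solved on a
20,001-point grid and inverted by interpolation). The warp's area scale at
the mapped point is exactly g², its two principal stretches bracket g and
average to it, so realized mean neighbor spacing tracks spacing·g to within
~1.5% everywhere — adequate for recovering diameter ratios within the 10%
the tests require. Ground-truth diameter per facet is 1000·spacing·g at the
pre-jitter position.

Facet count control: the oval outline is scaled uniformly (aspect preserved,
bisection on the realized point count) so the clipped cast holds the target
count; the lattice spacing the user sets is honored exactly. `n_target=None`
uses the outline as given. Fewer than 7 contained points is a degenerate
input.

Defaults are the study conditions: spacing 0.029 mm (≈ the ~29 μm average
facet diameter), amplitude 1.6 (≈ largest/average diameter ratio ~47/29),
gradient scale 0.5 mm, jitter SD 1 μm, outline 4.4 × 2.8 mm oval (≈ 9.7 mm²,
the scale of a large-male eye), 11,000 facets (within the 10,000–12,000
plausible range; no per-eye counts were published, so this is a plausibility
choice), seed 20180501. Tests and the bundled analyses run casts scaled down
to 1,200–3,000 facets; the spatial structure is unchanged and every
structural check is size-independent.

What the generator does *not* emulate: cutting/flattening distortion, cast
damage and cracks, non-elliptical outlines, the small-diameter tail near the
eye margin of real eyes (the synthetic minimum comes from jitter, not a
ventral gradient), and pixel quantization. Passing tests therefore show the
measurement chain is correct on clean hexagonal data, not that it is robust
to badly damaged casts.

## Synthetic regression datasets

For a target slope β, intercept, and sample R² on predictor x ~ Uniform(a,b)
(log10-transformed first for log-log entries), noise is Gaussian with
σ² = β²·Var(x)·(1−R²)/R², using the closed-form variance of the (log)
uniform distribution. OLS refits are then unbiased for β at any noise level,
and the mean realized sample R² lands within ±0.03 of target at n ≥ 18
(verified by simulation; at very small n sample R² is upward-biased, which
is why the calibration invariant is stated at n ≥ 18). The predictor is
uniform rather than matched to an empirical head-width distribution —
simpler, and sufficient for recovery testing. `eyemorph.calibrations` pins
the published regression configurations (slope, R², n, head-width span);
log-log intercepts are plausible values since only exponents were printed,
and the intercept never enters slope recovery.

One published equation is deliberately absent from the calibration set: the
large-male relative eye-height line (−0.09·head width + 0.37) produces
negative eye:head ratios over the printed head-width range and contradicts
the stated direction of the effect, so it is treated as a transcription
error. Likewise a printed female global-angle mean of 31.51° is inconsistent
with its own printed range (1.47°–1.58°) and is read as 1.51°.

## Problem sizes and determinism

Monte-Carlo protocols use 500 replicate datasets per configuration (recovery
means), 600–2,000 replicates for type-I-error calibration; these sizes put
the Monte-Carlo SE well below the effects being checked while keeping any
single protocol under a few seconds. All randomness flows through explicit
integer seeds (`numpy.random.default_rng`); fixed seed means bit-identical
output everywhere, including the SVG renderings.
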