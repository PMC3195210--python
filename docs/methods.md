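# Methods

`grassid` implements a classical image-analysis pipeline for telling apart
seedlings of wheat, annual ryegrass and brome grass — three narrow-leaf
grasses that look confusingly similar up to the four-leaf stage — from
top-view colour photographs of single plants. This note records the model,
the conventions and defaults, and the design decisions taken where the
method left genuine freedom.

## Segmentation

A pre-cropped single-plant image is converted to HSV. Pixels with
saturation below `saturation_min` (default 0.15) are treated as achromatic
background; of the rest, a pixel is foliage iff its hue lies in the
inclusive window `[54°, 154°]` — the range green plant material occupies
against a soil background. Connected components smaller than
`min_region_px` (default 25, 8-connectivity) are removed as salt noise;
setting it to 0 recovers the literal per-pixel rule. Achromatic pixels are
reported with hue 0, a convention that never matters because the
saturation gate excludes them first. An optional contrast stretch
(common min–max scale over all three channels) is available but off by
default: hue is invariant under it, so it is cosmetic.

Grayscale intensity is the BT.601 luma `0.2989 R + 0.5870 G + 0.1140 B`,
rounded half away from zero. Crop rectangles are 0-based, row-major and
half-open. The camera-geometry utility converts a field of view and a
sensor size to mm²/pixel and mm/pixel (square root), e.g. a
980 × 720 mm view on 3648 × 2736 px gives 0.07 mm²/px and 0.266 mm/px.

## The 11 features

Per pixel, with `I` the unrounded luma: `r_i = R/I`, `g_i = G/I`,
`b_i = B/I`; `RBI = (r_i − b_i)/(r_i + b_i)`; and the excess indices
`ERI = (r_i − g_i)(r_i − b_i)`, `EGI = (g_i − r_i)(g_i − b_i)`,
`EBI = (b_i − g_i)(b_i − r_i)`. Dividing by luma makes all seven invariant
to a common illumination scale. A pure-green pixel makes RBI 0/0; it is
reported as 0, flagged, and excluded from the region RBI mean. Pure-black
pixels are undefined and rejected.

The method defines per-plant features, but not how per-pixel colour values
become one number per plant; we use the arithmetic mean over mask pixels —
the standard regionwise statistic, and the only aggregation consistent
with a single value per plant feeding a correlation matrix.

**Erosion width `W`** is twice the number of successive morphological
erosions with a 3×3 square kernel (image border counts as background)
needed to empty the mask. A bar of width `w` gives `W = 2·ceil(w/2)`, so
`W` is always a positive even integer — a quantized leaf-width proxy. We
erode until *empty* (not until one pixel remains); the alternative differs
by at most one iteration and is noted as an open convention.

**Waddle Disk Ratio** `WDR = W / (2·√(A/π))` with `A` the mask pixel
count: erosion width over the diameter of the equal-area disk. It measures
linearity of the foliage (long thin leaves → small WDR). Note a geometric
subtlety: a square kernel erodes a *disk* along its diagonal, removing
about √2 of Euclidean radius per iteration, so even an ideal disk has
WDR ≈ 1/√2 ≈ 0.71, not 1. The ratio is still monotone in elongation,
which is all the discrimination uses.

**Texture**: with `p(z_i)` the proportions of the 256-level grayscale
histogram over mask pixels, uniformity `U_t = Σ p²` and entropy
`E_t = −Σ p log₂ p`. Base-2 logarithms (bits); the base only rescales
`E_t` and cancels in correlations and standardized PCA. The two move
oppositely by construction and are strongly anti-correlated in practice.

Multi-leaf plants are eroded as one region, so `W` reflects the widest
surviving structure (the leaf junction at the base adds at most a couple
of iterations).

## Feature selection

Pearson correlations (raw features; Pearson is scale-invariant so this
matches the correlation-matrix PCA downstream) feed a greedy filter: scan
features in a fixed priority order, keep a feature iff its |r| with every
already-kept feature is strictly below 0.7. The default priority promotes
`r_i, RBI, EBI, W, WDR, U_t`; on the bundled reference correlation matrix
this reproduces exactly that six-feature subset. The rule is threshold-
inclusive (|r| ≥ 0.7 counts as redundant). One structural caveat: the
identity `0.2989 r_i + 0.5870 g_i + 0.1140 b_i ≡ 1` means keeping all
three normalized factors creates an exactly singular correlation matrix;
the PCA below is written to tolerate this.

## Rotated PCA and scoring

Features are z-scored with the sample SD (n − 1). The sample correlation
matrix is eigendecomposed; loadings are eigenvectors scaled by
√eigenvalue with each column's dominant entry made positive. Components
with eigenvalue ≥ 1 − `kaiser_tolerance` are retained; the default
tolerance 0.05 encodes scree-plot practice of admitting an eigenvalue
that prints as 1.00.

Retained loadings are rotated by classical Varimax — successive planar
rotations with the closed-form optimal angle per column pair — with
Kaiser row normalization by default (the convention of the major
statistics packages). Sweeps stop when the criterion improves by < 1e-8
(100-sweep cap; hitting the cap emits a RuntimeWarning and returns the
best iterate, since an exception could not also deliver a result).
Columns are ordered by decreasing sum of squared loadings with dominant
entries positive, making fits bit-reproducible. The rotation is verified
orthogonal and communality-preserving, and the implementation is tested
against a brute-force grid search over planar angles.

Component score coefficients follow the regression method `C = R⁻¹·Λ`,
which yields fitting-set scores with mean 0, variance exactly 1, and zero
mutual correlation. Internally the fit computes the algebraically
identical `C = V_k D_k^{−1/2} T` (retained eigenvectors, eigenvalues, and
rotation), which stays finite when discarded eigenvalues are zero — the
exact-collinearity case above. Scoring a new plant is: standardize by the
model's means/SDs, multiply by `C`. A published six-feature coefficient
matrix from a greenhouse study of these three species ships as a
reference profile for scoring pre-standardized rows without refitting.

## Discrimination

Per retained component, a one-way ANOVA across species (upper-tail F
probability) and Bonferroni-adjusted pairwise comparisons using the
pooled within-group mean square, `se = √(MS_w (1/n_a + 1/n_b))`, p-values
multiplied by the number of pairs and capped at 1. Group descriptives use
Student-t 95% confidence intervals for the mean.

For each species pair a component separates, the decision threshold is
the **midpoint of the gap** between the two groups' CI bounds — the
method says only "a value in between", and the midpoint is the
deterministic choice; it is overridable. Overlapping CIs raise an error
rather than guess. A score strictly above the threshold predicts the
high-mean species; ties go to the low side (documented, testable).
Accuracy is correct/total over the two species' images.

The reference study's pairing plan (component 1: ryegrass high vs wheat;
component 2: brome high vs wheat; component 3: ryegrass low vs wheat)
ships as `DEFAULT_PLAN`. A refit on new data gives components whose
order, sign and content are data-dependent, so the pipeline instead picks,
per species pair, the retained component with the widest CI gap on the
training set (`suggest_plan`). Holdout evaluation is a uniform random
split without replacement, `round(fraction·n)` test rows (20% of 286 →
57/229), deterministic under its seed.

## Synthetic seedlings

The greenhouse images behind the reference tables are not deposited, so a
generator provides labelled imagery. Each plant is 1–4 tapered,
constant-curvature strokes radiating from a base point on a soil-coloured
background (hue ≈ 25°, outside the foliage window); colour interpolates
base→tip, with additive red concentrated at the leaf base, an additive
blue tint, and multiplicative grayscale speckle (hue-preserving) that
maps directly onto `U_t`/`E_t`. The ground-truth mask is recorded at
rasterization, so segmentation can be scored pixelwise. Per-plant
redness and blue tint are drawn independently (truncated normal): real
plants vary on these axes separately, and without the independent
variation the colour block becomes a single axis that the |r| ≥ 0.7
filter collapses into one feature, discarding the blue information that
separates brome.

Default species parameters (pixels on a 180×180 canvas; colour shifts in
0–255 units):

| parameter | wheat | ryegrass | brome | encodes |
|---|---|---|---|---|
| leaf width (mean ± sd) | 7.5 ± 0.7 | 3.5 ± 0.4 | 6.5 ± 0.8 | ryegrass's much narrower leaves |
| leaf length | 55 ± 8 | 60 ± 8 | 55 ± 8 | similar lengths |
| base red boost | 0 | 50 | 18 | reddish bases of the weeds |
| blue tint | 0 | 0 | 15 | brome's bluish-green foliage |
| texture speckle sd | 0.02 | 0.12 | 0.06 | hairless/uniform vs rougher surfaces |
| red boost sd / blue tint sd | 5 / 4 | 5 / 4 | 5 / 4 | independent per-plant colour variation |

These contrasts give roughly 3 pooled within-class SDs of separation on
each pair's discriminating features (width/texture/redness for
wheat–ryegrass, blue content for wheat–brome) — a deliberate reading of
the expert descriptions ("narrower leaves", "bluish green") as clear
visual differences. At 2 SD of single-component separation, a
CI-midpoint threshold's expected accuracy is only Φ(1) ≈ 84%, so weaker
contrasts would not represent species an expert can tell apart. The
blue-tint spread is capped (sd 4) so worst-case brome hue stays ≈ 150°,
inside the segmentation window.

What the generator does *not* emulate: perspective and self-occlusion,
specular soil texture and stones, shadows, illumination gradients,
anti-aliased leaf edges, botanical leaf shape (ligules, auricles, blade
twist), and growth over imaging dates. Passing tests therefore show the
pipeline's stages are correct and that the method recovers injected
structure; they do not certify the reference study's accuracy figures on
real greenhouse imagery, which are not reproducible without the original
images.

## Problem sizes and numerics

The end-to-end rehearsal (tests and acceptance script) uses the reference
study's class sizes — 118 wheat, 122 brome, 46 ryegrass; 229 train / 57
test — on 180×180 px canvases, which runs in a few seconds. Property
suites use ≤ 32×32 masks against a pure-Python erosion oracle, random 6×3
loadings against a 1441-angle grid-search rotation oracle, and 3-factor
recovery at n = 500. Varimax convergence tolerance is 1e-8 on the
criterion; eigenvalues are clipped at 0 before the √; degenerate inputs
(constant features, empty masks, single groups, zero within-group
variance, overlapping CIs) raise typed exceptions rather than produce
numbers.

## Known limitations

- Single-plant images only: no detection or separation of multiple plants
  in a scene.
- The pairwise thresholds do not fuse into a calibrated 3-way classifier;
  the pipeline reports per-pair accuracies, as the method does.
- Greedy selection is order-dependent by design; a different priority can
  keep a different (equally valid) low-correlation subset.
- `W` is quantized to even integers, which limits width resolution to
  2 px and makes WDR slightly lumpy for thin plants.
- The reference coefficient profile can score only pre-standardized
  feature rows, since the original standardization parameters were never
  published.
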