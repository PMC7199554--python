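# Methods

This note documents the models and numerical choices behind `retimosaic`:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely open.

## Registration model and its assumptions

The camera is assumed to rotate about its optical centre between exposures,
so a pixel `p` maps to a viewing ray `r = R·K⁻¹·p` with shared intrinsics
`K = [[f,0,cx],[0,f,cy],[0,0,1]]` and a per-image rotation `R` (identity for
the reference image). Under this model any two images are related exactly by
the homography `H_ij = K·R_jᵀ·R_i·K⁻¹`. For fundus photography this is an
approximation twice over — the eye is a curved surface, and the camera also
translates slightly — but over the narrow fields of a fundus series the
rotation-only model is the standard and effective choice, and it is what
makes a seam-free spherical mosaic well-defined at all.

Only ray *directions* are observable under a rotating camera, so wherever
back-projections of matched points are compared (bundle adjustment, the
matching RMSE), rays are normalised to the unit sphere; exact
correspondences under the true cameras then score exactly zero. Bundle
adjustment scales those unit-ray residuals by the shared focal length:
at fixed `f` this is a constant rescaling that moves no optimum, but it
removes the spurious descent direction in which inflating `f` collapses all
rays toward the optical axis, and it makes the cost pixel-comparable
(`f`·angle ≈ arc length in pixels).

## Stage-by-stage notes

**Binarization and thinning.** Probability maps are cut at 0.5 (inclusive);
8-bit inputs are first scaled by 1/255. Thinning implements the classic
two-subiteration parallel rules (delete when 2 ≤ B(p) ≤ 6, A(p) = 1 and the
subiteration's two neighbour products vanish), iterated to a fixed point
with background-padded borders. The result never contains a solid 2×2
block, adds no pixels, is idempotent and preserves 8-connected component
counts on vessel-like shapes; all four properties are tested.

**Structuring-element bank.** A skeleton pixel is a Y/T branch point when
three of its eight neighbours are set in pairwise non-adjacent ring
positions. Enumerating all such triples gives 16 elements (4 orthogonal "T"
forms, 4 all-diagonal "Y" forms, 8 mixed), closed under 90° rotation. The
default bank is this complete set: a hand-picked 14-element subset cannot be
reconstructed from first principles, and the complete bank preserves the
stated Y/T semantics plus rotation equivariance. A custom bank (any subset)
can be loaded from a plain-text file.

**Accumulation and extraction.** The running weighted mean over the bank
equals the arithmetic mean of all eroded images to machine precision (each
image contributes weight `1/n`, `1/14` for a 14-element bank; verified by
indicator probing against a brute-force mean). A pixel is a candidate when
*any* element retained it (union semantics): since nearby pixels of a
crossing satisfy different elements, demanding full agreement would discard
almost every junction. 5×5 raster-order suppression keeps the first
candidate of each cluster; this off-centre tie-break is deterministic but
makes composite detection equivariant only up to the window for
cluster-producing junction shapes.

**Descriptors.** Morphological detection has no scale space, so every
keypoint carries a fixed working scale `s` (default 2 px; configurable).
Orientation uses Haar filters of side 4s with Gaussian weighting σ = 2.5s
on the 6s disc, a π/36 sliding-window step, and the continuous resultant
angle of the winning π/3 window; constant neighbourhoods return 0 by
convention. The descriptor window (20s, 4×4 subregions, 5×5 samples,
filters of side 2s, σ = 3.3s) is normalised to unit length so monotone
illumination scaling cancels exactly. Two robustness additions beyond the
minimal construction, both standard practice for gradient descriptors:
a keypoint whose orientation histogram has near-tie modes (within 80 % of
the winner and > π/3 away — vessel junctions are inherently three-modal) is
emitted once per mode; and when keypoint positions are available the ratio
test skips second-nearest candidates within 3 px of the nearest, so a
point's own duplicate orientations never act as its ratio competitor.

**Matching and verification.** One-way ratio matching at 0.3 (strictly
greater is rejected; ties break to the lower index). RANSAC samples 4
matches without replacement, counts inliers at reprojection error ≤ 3 px,
stops early at the p = 0.99 adaptive bound (cap 2000 iterations), and
re-fits on the consensus set *iteratively* until the inlier set is the
fixed point of its own least-squares fit — a single re-fit can leave the
model measurably biased by borderline points. The homography solver is the
normalized (Hartley) DLT with a smallest-singular-vector solution; an
independent implementation from scikit-image serves as a cross-check in the
tests. Pair confidence is `inliers / (8 + 0.3·matches)` with acceptance
threshold 1.0 (range 0.5–1.5), the standard panorama verification rule.

**Focal estimation.** Each homography, conjugated into principal-point
-centred coordinates, yields a closed-form focal estimate from the
orthonormality of `K⁻¹HK` (two branches; a branch is used when its
denominator exceeds 1e-8 and the squared focal is positive). Both `H` and
`H⁻¹` are evaluated and the median over all pairs is taken. For
near-pure-pan pairs the first branch's denominator is nearly zero and noise
occasionally produces order-of-magnitude outliers, so the pipeline restricts
estimates to a physically plausible window (f between 0.25× and 6× the frame
size, i.e. fields of view between about 7° and 110°) and falls back to
1.8× the frame size when nothing usable remains; bundle adjustment then
refines the value.

**Rotation chaining and bundle adjustment.** Rotations propagate from the
reference along a maximum-spanning tree weighted by inlier counts, each
step projected back to the nearest orthonormal matrix (SVD polar
projection). Bundle adjustment optimises one shared focal plus a local
axis-angle increment per non-reference image by Levenberg–Marquardt with
numerically differentiated Jacobians: damping ×10 on rejection, ÷10 on
acceptance, accepted steps never increase the cost, convergence at relative
cost change < 1e-8 or 100 iterations. Principal points stay fixed at the
frame centre.

**Warping, gain, blending.** Destination pixels are inverse-mapped through
the spherical parameterisation (azimuth via the two-argument arctangent,
`R⁻¹ = Rᵀ` by orthonormality) and sampled bilinearly; validity footprints —
for real photographs, the illuminated circular field found by thresholding,
largest-component selection and hole filling — are warped nearest-neighbour.
The mosaic-plane scale is the estimated focal, keeping near-identity warps
at unit magnification. Gains minimise the regularised pairwise overlap
mismatch (σ_N = 10, σ_g = 0.1); with those weights the correction is
deliberately partial (two layers whose overlap means are 150/75 settle at a
gain ratio of ≈1.63, the closed-form solution of the 2×2 normal equations),
leaving the remainder to the blender. Blending composites layers
sequentially in input order: per 5-level Laplacian pyramid (5-tap binomial
kernel, ceil-halved dims), each level is convexly combined through the
Gaussian pyramid of a distance-based seam mask (the incoming layer claims
overlap pixels deeper inside its own footprint). Pyramid expansion uses
zero-insertion followed by *normalised* 5-tap smoothing, which reproduces
constants exactly at borders; reconstruction is exact by construction.
Invalid regions are pre-filled with their nearest valid pixel so pyramid
smoothing cannot bleed black borders into a seam. The order-dependence of
sequential compositing is intentional and documented.

## Synthetic scenes: what they emulate, and what they do not

`synthetic` generates a flat textured "retina" canvas with a vessel tree
grown by recursive binary branching (trunk width 5 px, children ×0.75 down
to 1 px, separations 30–70°, junctions ≥ 26 px apart and ≥ 10 px from the
border), rendered through rotation-only cameras sharing centred intrinsics.
Default imaging conditions are chosen to emulate fundus photography at the
700×605 working resolution: a 30° horizontal field (f ≈ 1.87× frame width,
1300 px), dark vessels (60) on a bright textured field (170) with
multi-scale texture standing in for the choroidal/nerve-fibre pattern,
mild optical blur (σ = 1.2), radial vignetting (12 % at the field edge), a
circular illuminated field (radius 0.49× frame width) and Gaussian pixel
noise σ = 2. Overlap targets refer to the circular fields, as fundus
overlap percentages do, and are realised by bisecting the pan angle against
the measured footprint overlap. Junction density (~one per 57 px square)
gives a frame ≈130 detectable bifurcations, comparable to real vessel-mask
feature counts. Everything is deterministic per seed.

Two properties deserve emphasis:

- **Ground truth is as-rendered.** Rasterising finite-width strips
  displaces the apparent branch point of a shallow-angle junction a few
  pixels up the bisector, so recorded junction coordinates are snapped to
  the skeleton's branch pixel (cluster raster-first). In strict mode
  (default, used for detection tests) generation is retried
  deterministically until rendered branch points and recorded junctions
  agree one-to-one; in sequence mode one drawing is kept and only certified
  junctions enter the ground-truth list.
- **The canvas is planar.** This makes the rotation-only homography model
  *exact*, enabling true parameter-recovery tests, but it tangent-stretches
  views at large pan angles in a way a curved retina does not: beyond a
  total span of roughly ±60° the extreme views of a long sequence become
  appearance-distorted enough that strict ratio matching starts to fail at
  their overlaps. Multi-view demonstrations therefore use up to 5–9 views
  with spans inside that regime. Passing tests on these scenes show the
  pipeline's geometry and photometry are correct under its own model; they
  cannot show robustness to curvature, parallax, pathology or segmentation
  errors in real eyes.

Matching difficulty in this synthetic world is driven by three error
sources measured during design: detector localisation jitter (±1 px between
views, which is why the finest texture scale is kept at a ~3 px correlation
length), resampling/foreshortening between views (why the default field of
view matters), and sensor noise (minor). The strict 0.3 ratio passes
roughly a third of true correspondences under the default conditions —
enough that pairs overlapping by ≥ ~50 % clear the confidence gate with a
comfortable margin, while low-overlap pairs (≈25–35 %) may be rejected;
the same qualitative behaviour real fundus pairs show, where the
lowest-overlap pairs are the hardest to register.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| binarize threshold | 0.5 | inclusive vessel-probability cut |
| working size | 700×605 px | processing resolution |
| bank | full 16 | all valid 3×3 Y/T elements |
| suppression window | 5 px | one detection per 5×5 cluster |
| descriptor scale s | 2 px | window 40 px, filters 4 px |
| ratio | 0.3 | nearest/second-nearest acceptance |
| RANSAC t, iters, p | 3 px, 2000, 0.99 | verification |
| confidence | 1.0 (0.5–1.5) | pair-acceptance threshold |
| pyramid levels | 5 | multiband blending depth |
| gain σ_N, σ_g | 10, 0.1 | overlap noise / gain prior |

## Known limitations

- No translation/parallax or radial-distortion modelling; the rotation-only
  model is assumed, not estimated against alternatives.
- Vessel segmentation quality is taken as given; only a trivial threshold
  fallback is provided.
- Sequential blending is order-dependent; no graph-cut seam optimisation.
- The synthetic generator does not model pathology (haemorrhage, tumour),
  the optic disc or macula, eye curvature, or segmentation noise in the
  vessel masks.
- Focal estimation assumes a single shared focal and centred principal
  point across the series.
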