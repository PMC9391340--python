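# Methods

This note documents the models and procedures wsiseg implements, the
parameters that matter, the synthetic fixture's scope, and the numerical
conventions a user relying on exact reproducibility should know.

## Coordinate and raster conventions

All public APIs use 0-based, half-open pixel coordinates at base
resolution, `x` = column, `y` = row. `read_region(x, y, w, h, d)` returns a
raster of `round(w/d) × round(h/d)` pixels, reading from the deepest
pyramid level whose downsample does not exceed `d` and resampling
bilinearly when `d` is not a stored level; requests beyond the slide bounds
are padded with white (255, 255, 255) so edge patches of an inference grid
are always full size. Output pixel `j` at downsample `d` covers the base
interval `[x + j·d, x + (j+1)·d)`, with its center at `x + (j + 0.5)·d`.

Polygon rasterization marks a pixel when its center lies strictly inside
the ring (even–odd rule). With integer-ish vertices and half-integer
centers this is deterministic and reproducible by brute-force
point-in-polygon, which is how the tests check it. When polygons of
different classes overlap, later layers overwrite earlier ones — layer
order is the precedence order (the format itself does not specify a rule,
so this is fixed by convention and documented). Mask vectorization traces
the 0.5 iso-level between foreground and background pixels of each
connected component, so a rasterize → vectorize → rasterize round trip
recovers blob-like components to IoU ≥ 0.98; thin one-pixel structures can
lose more at the boundary.

## Tissue masking

"Fast color thresholding" is operationalized as: tissue where
`min(R, G, B) < 228` after Gaussian smoothing (σ = 1 at the mask scale),
then connected components under 100 px removed; pure-white source pixels
are never tissue. The threshold and morphology values are documented
defaults chosen for white-background brightfield slides, not a reproduction
of any particular system's (unpublished) rule. The mask is computed at
downsample 32 by default — appropriate for gigapixel scans; for the
kilopixel synthetic fixture the package's own tests use downsample 8, since
at 32 the whole fixture mask is 32 × 32 px and the 100 px cleanup would
erase real tissue. Masks are cached as PNG under a content-addressed
filename when a cache directory is given, and reload bit-exactly.

## Training-patch sampling

Stochastic choices per draw, in fixed order (so one seed reproduces the
stream bit-exactly): downsample factor uniform over `downsample_list`
(default 1, 2, 3, 4); background branch with probability `background_prob`
(default 0.1) — the location is then unconstrained; otherwise, with
balancing on, target class uniform over classes that have polygons
(empty classes are skipped with a warning), polygon uniform within the
class, center jitter uniform in ±(patch/2 − 2)·d per axis. Balancing is
*probabilistic* (uniform class probability per draw) rather than a
per-step quota; the underlying intent — counteracting uneven class
abundance — does not dictate a mechanism, and the probabilistic form is
stateless and testable by empirical frequency. The jitter bound keeps the
chosen polygon's representative point strictly inside the patch, so every
balanced draw contains at least one pixel of its target class. Ignore
regions are written as `ignore_label` (default 255) after class
rasterization and are excluded from the loss and from balancing
statistics.

## Reference segmenter and trainer

The production-scale networks this pipeline is normally wrapped around
(output stride 16, decoder output stride 4, tens of millions of weights)
are deliberately not reproduced. The package fixes the *contract* —
`(H, W, 3)` uint8 in, `(H/s, W/s, n_classes)` float logits out, `s` the
decoder output stride (default 4), deterministic given fixed weights — and
provides:

* `ReferenceSegmenter`: fixed s×s average pooling, input standardisation
  `(x − 128)/40`, conv3×3(16) → ReLU → conv3×3(16) → ReLU, and a 1×1
  classifier over the concatenation of those features with the pooled
  color (a skip connection that lets color-separable classes be learned
  quickly); pure numpy with hand-written backprop. He initialisation from
  a seeded generator; training is bit-deterministic.
* `ColorPrototypeSegmenter`: an analytic nearest-prototype-color model
  honoring the same contract, used as a deterministic stand-in in
  stitching tests.

Training: mini-batch SGD, momentum 0.9, base learning rate 1e-3 with
polynomial decay `lr₀(1 − t/T)^p`; the decay power (0.9) and end rate (0)
follow the convention of the widely used segmentation implementations,
since they are rarely printed. Defaults `steps = 500`, `batch_size = 2`,
`patch_size = 512` (tests use 96–128 px patches — the fixture objects are
small). The loss is pixel-wise cross-entropy with ignore masking; the
function itself is an assumption, as papers in this family often leave it
unnamed. By default the loss is inverse-frequency class-weighted using
label counts tracked over the stream: the unannotated background majority
(>90 % of pixels even under balanced sampling) otherwise dominates the
gradient and rare structure classes converge far too slowly for a 500-step
budget. A `train_batchnorm` flag exists for contract parity with wrapped
networks; the reference model has no batch-norm layers.

Checkpoints are numpy `.npz` archives holding the weights plus a JSON
metadata record (hyperparameters, class names); loading restores
bit-identical predictions.

## Tiled inference and stitching

Grid origins lie on the stride lattice in prediction-downsample
coordinates, row-major, with the final origin per axis clamped to the
slide edge and rounded *up* to the `origin_align` lattice (default 4, must
be a multiple of the decoder output stride) so accumulation stays aligned
with the logit grid; the patch may then overhang the edge into white
padding. Patches that do not intersect tissue are skipped; every tissue
pixel remains covered by at least one patch.

Border trimming: a logit pixel contributes only when its full s-wide
footprint lies at least `border_trim` patch-pixels from the patch border.
Trimming is suppressed on sides where the patch abuts or overhangs the
slide boundary — otherwise a rim of tissue would never be predicted
(the source systems do not state their behavior there). Overlap averaging
is unweighted, in float64; both the contour and heatmap output modes
average logits before any argmax. Argmax ties break toward the lower class
index; pixels with zero contributions are background.

Scale relations under the defaults: logit maps are 25 % of the patch per
side (stride 4), and with prediction downsample 2 the assembled whole-slide
mask is `base // 8` per side. Heatmaps are sparse softmax probabilities of
one class over the covered region, keeping entries ≥ a threshold (default
0.05 — "sparse" is the stated goal, the cut-off is this package's rule),
with coordinates multiplied back to base resolution on export.

## Morphometry

The full several-hundred-feature catalogues used in glomerular phenotyping
live in dedicated prior literature; this package fixes a named, versioned
subset (`v1`, 22 columns + optional `area_um2`): raster area, polygon
perimeter, circularity 4πA/P², eccentricity, solidity, extent,
bounding-box aspect, equivalent diameter, centroid and bbox, RGB mean/SD
inside the polygon, and hematoxylin/eosin mean/SD after Ruifrok–Johnston
color deconvolution (the standard stain vectors shipped with
scikit-image). The perimeter is taken from the polygon geometry rather
than raster step-counting, which is biased upward for smooth contours
(a digital disk's step perimeter inflates by ~5 %, pushing circularity
well below 1). Areas are reported in µm² only when microns-per-pixel is
known; degenerate zero-area polygons are dropped with a warning. Custom
features can be added via `extra_features` callables.

Percent IFTA = 100 × (IFTA ∩ cortex) / cortex, computed by rasterizing
both layers over the cortex bounding box (default downsample 2); zero
cortex area is an error.

## Evaluation

Pixel metrics are one-vs-rest per class from a confusion table, closed
forms, with degenerate denominators reported as 0 plus a `degenerate`
flag. ROC sweeps softmax probabilities (a monotone transform of the
logits, leaving AUC unchanged) over covered pixels only, with trapezoidal
AUC; the tests verify equality with the Mann–Whitney statistic. ICC(2,1)
is computed from two-way ANOVA mean squares with the F test of r = 0
versus r > 0; the implementation is cross-checked against an independent
variance-component oracle and against pingouin's ICC(A,1) row.

Separability embeds the feature rows to 2-D with UMAP (seeded) and
cross-validates a KNN classifier on the embedding, reporting Cohen's kappa
per neighborhood size over an odd 1–25 grid (the grid is this package's
default; sources describing the analysis do not state one) and the
maximum. Folds default to 10; descriptions of this analysis disagree
between five- and ten-fold cross-validation, so the fold count is an
explicit parameter.

## Synthetic fixture: what it does and does not show

The generator draws rotated elliptical tissue blobs in a flat eosin-like
pink on white, then places non-overlapping elliptical objects (defaults:
12 "glomerulus" ellipses of 16–34 px semiaxis, 16 "tubule" ellipses of
9–20 px) fully inside tissue by rejection sampling, coloring each with a
distinct class color ± uniform noise of 6 gray levels. Objects are drawn
by rasterizing their own ground-truth 64-gon, so drawn pixels and
annotation agree by construction. Slides are 1024 × 1024 px, three pyramid
levels, nominally 0.25 µm/px — roughly a 40× scan shrunk ~40-fold. Because
the fixture is small, the package's own tests predict at downsample 1
rather than the gigapixel default of 2, and compute tissue masks at
downsample 8 (see above).

Passing tests on this fixture demonstrate the *pipeline* — geometry,
sampling distributions, stitching arithmetic, interchange fidelity,
trainability of a color-separable task — not histologic segmentation
skill: real tissue has textured, overlapping, color-ambiguous structures,
stain variation, and scanner artifacts that a 3-layer color model cannot
resolve. Performance figures quoted on the fixture therefore say nothing
about clinical WSIs.

## Problem sizes used by the shipped checks

The test suite and acceptance script size their computations for a single
CPU: 1024 px fixture slides, 10,000 sampler draws for frequency estimates
(binomial 3σ ≈ 0.009 at p = 0.1), 500 training steps at 128 px patches,
stitching-oracle comparison with 256 px patches / 128 px stride / 10 px
trim, and n = 200 × 315-dimensional clusters for the separability check.

## Known limitations

* `read_region` holds pyramid levels in memory; it targets desk-scale
  slides (≤ ~100 megapixels), not true gigapixel streaming.
* Polygons with holes are not modelled (a component's outer contour only);
  point/line annotations are out of scope.
* The reference segmenter is a color model; it exists to exercise the
  contract, not to segment real tissue.
* Heatmap JSON stores base-resolution coordinates; reconstructing grid
  indices for non-power-of-two scale factors can introduce float rounding.
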