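# Methods

## The synthetic face benchmark

No public corpus of lateral head-fixed mouse faces with per-frame state
labels exists, so the package ships a generative stand-in that is the
canonical input for every stage. One frame is a head ellipse on a
distractor background carrying five parts: an ear ellipse, an eye
ellipse, a mouth (thin closed band, or band plus an open dark cavity), a
jaw polyline (jaw point → mouth point → nose point) and the nose
landmark. Each part is rendered analytically, so the generator emits
exact boolean part masks and the generative parameters alongside the
image — downstream saliency and morphometry can be scored against ground
truth rather than against hand annotation.

State-dependent deformations follow the qualitative directions reported
for the three conditions:

| field (units) | neutral | tail-pinch | brushing |
|---|---|---|---|
| ear eccentricity | 0.45 ± 0.11 | 0.72 ± 0.09 | 0.70 ± 0.09 |
| ear angle (°) | 30 ± 14 | 62 ± 16 | 95 ± 16 |
| eye eccentricity | 0.55 ± 0.08 | 0.55 ± 0.08 | 0.72 ± 0.08 |
| eye angle (°) | 20 ± 10 | 20 ± 10 | 50 ± 18 |
| jaw interior angle (°) | 170 ± 5 | 153 ± 8 | 140 ± 8 |
| P(mouth open) | 0.03 | 0.92 | 0.25 |
| mouth gap (px @256) | — | 9 ± 2 | 5 ± 1.5 |

All distributions are truncated normals (resampled into bounds, clipped
as a last resort). The spreads are deliberately calibrated so that
**adjacent states overlap by roughly ±2 SD on every single feature**
while the joint deformation pattern separates cleanly — mirroring the
observation that no single facial parameter draws a clean boundary but a
multivariate embedding does. Quantitative effect sizes are not reported
for the real stimuli; only these directions are grounded, the magnitudes
are this package's choice and are frozen.

Anti-shortcut rule: head center and size, global brightness
(U(0.85, 1.15)) and the background (uniform or low-contrast sinusoidal
texture, base color U(150, 215) per channel) are sampled independently
of the state, so a classifier cannot exploit non-facial cues.

What the generator does *not* emulate: fur and whisker texture,
illumination gradients, perspective/pose variation, temporal
autocorrelation of video frames, and inter-animal identity structure.
Consequences: a classifier that succeeds here has only been shown to
exploit geometric part deformations under clean segmentation; the
frame-rate/window fields (5 Hz, 5 s) are carried as metadata only, and
per-animal grouping of the hold-out split is not modeled.

Scales: the default profile renders 256 px frames (used for
morphometry); a 64 px "tiny" profile drives the desk-scale classifier
experiments. All geometry scales linearly.

## Preprocessing

Subject detection is a self-contained background-model segmenter: the
median color of the 2-px border is the background estimate, pixels more
than 70 RGB-Euclidean units away are foreground, a disk-3 morphological
closing fills thin structures and the largest connected component is
kept. Frames without a plausible component (< 0.5 % of pixels) raise a
detection failure and are excluded, the same policy as dropping unusable
video sequences. Any external detector can replace this step by
supplying its mask to `composite` directly. Compositing writes the
uniform background RGB [200, 167, 122] exactly; foreground pixels are
copied verbatim. Resizing stretches to 227 × 227 (bilinear,
anti-aliased); no padding or translation, so part coordinates remain
comparable across frames. An input already at target size passes
through bit-identically.

## Dataset building

Balancing down-samples every class, uniformly without replacement, to
the minimum class count; retained indices stay sorted so balancing is
pure selection. The hold-out split is stratified per class at
64 : 16 : 20 with a floor rule (train and validation take the floors of
their exact shares, the remainder goes to test), making all counts
integers without ever shrinking the test set. Augmentation — applied
online to training batches only — flips up–down with probability 0.5
(the literal reading of "vertical flipping"; the axis is configurable)
and translates by integer offsets uniform in [−30, 30] px at the 227-px
network scale, scaled proportionally (±8 px) for 64-px desk runs so the
augmentation severity is comparable. Vacated pixels take the uniform
background color, so augmentation cannot introduce border artifacts.

## Classifier and training protocol

The network is the fire-module (SqueezeNet) design: stem 3×3/stride-2
convolution, max-pooling, fire modules (1×1 squeeze → parallel 1×1 and
3×3 expands, concatenated; squeeze channels < total expand channels,
expands split evenly), a 1×1 class convolution, global average pooling
and softmax. Two variants:

* **v1.1** — 227-px input, stem 64, the canonical eight-fire widths,
  norm-free;
* **tiny** — 64-px input, stem 24, two fire modules (12/24+24,
  24/48+48), with batch normalization after every convolution.

Everything (forward, backward, SGD) is NumPy; analytic gradients match
central finite differences to < 1e-4 relative error in the test suite,
and the same backward machinery supplies Grad-CAM's feature-map
gradients.

Training protocol: mini-batch SGD with momentum 0.9 on cross-entropy,
110 iterations ("iteration" = one mini-batch update, not an epoch) with
one validation every 10 iterations, batch capped at the training-set
size. The reference configuration (batch 512, learning rate 3e-4) is
the published fine-tuning protocol and assumes ImageNet-pretrained
initial weights; pretrained weights require an external download, so
the default here is seeded random (He) initialization with a
`weights_file` hook for any portable archive. A randomly initialized
norm-free network cannot break symmetry in 110 iterations at any stable
learning rate, which is why the tiny variant carries batch
normalization; its desk protocol is batch 256, learning rate 0.3,
momentum 0.9 — calibrated once on training-set convergence and then
frozen. After the last iteration the BN running statistics are
recomputed exactly over the un-augmented training set (the exponential
averages otherwise lag the final weights). Momentum coefficient and
input normalization (pixels to [−0.5, 0.5]) are unstated in the source
protocol and documented here as package choices. Divergence (non-finite
loss) raises a training error carrying the iteration index.

Determinism: a single global seed fans out to per-stage child seeds via
an FNV-style hash; in single-threaded NumPy the full pipeline is
bit-reproducible.

## Grad-CAM

For a target class c and a convolutional layer with activations A_k,
the channel weights are the spatial means of ∂(logit_c)/∂A_k; the map
is ReLU(Σ_k α_k A_k), max-normalized to [0, 1] (per image — overlay
intensities are therefore not comparable across images) and bilinearly
upsampled to the input size. The default target layer is the last
convolutional feature layer before global average pooling. The
finite-difference oracle perturbs every element of the captured
activation (central differences, re-running only the network tail) and
must agree with the backprop route to 1e-3; this is asserted in the
suite on a norm-free toy network. Top-k reporting selects, per state,
the k = 5 test images with the highest posterior among images
*predicted* as that state (stable tie-break by image id) and writes
alpha-blended jet overlays.

## Morphometry

Ellipses are fitted by second central moments: semi-axes are twice the
square roots of the eigenvalues of the pixel-coordinate covariance
(which reproduces the axes of an ideal filled ellipse; cross-checked
against `skimage.measure.regionprops` in the suite), orientation is the
major eigenvector's angle. Angle convention throughout: degrees in
[0, 180), measured against the horizontal in image coordinates with y
down. A fit with (a − b)/a < 1e-3 has no meaningful major axis and
reports its angle as missing. Eccentricity is √(1 − (b/a)²); perimeter
uses Ramanujan's second approximation (relative error < 1e-6 at mild
eccentricities, verified against the exact elliptic integral). The jaw
angle is the interior angle at the mouth vertex between the jaw–mouth
and mouth–nose lines; the ear-to-eye angle/distance use fitted
centroids. Mouth opening is binary: from a mask, the gap is the mask's
extent along its minor axis minus the closed-lip band thickness (3 px at
the 256-px scale), thresholded at τ = 2 px; both constants are
configurable and stand in for by-eye scoring. Missing parts propagate
as NaN, never as silent zeros. On real images the part source would be
an annotation JSON (polygons + landmarks); automatic part segmentation
is out of scope.

## State space

The ten-parameter table is z-scored column-wise with sample SD
(ddof = 1); the binary mouth column is standardized like the others.
Zero-variance columns are excluded with a warning rather than divided.
PCA is an eigendecomposition of the sample covariance with a
deterministic sign convention (largest-magnitude loading positive);
explained-variance fractions are non-increasing and the eigenvalue sum
equals the column count on standardized data (asserted to 1e-8).
Separation in the embedding is summarized by the mean silhouette
coefficient (scikit-learn); classes with one member are excluded with a
warning. `coverage_2sd` reports the percent of a stimulated state's
values above / below / within the neutral mean ± 2 SD band, the
shaded-interval statistic used for per-parameter comparisons.

## Numerical and degenerate-input choices

* float32 weights/activations for speed; float64 available for
  gradient checks.
* Max-pooling is 2×2/stride-2, floor mode (the canonical 3×3/stride-2
  overlapping pooling is not reproduced; all tiny-variant feature sizes
  are powers of two so nothing is cropped).
* Softmax is computed with max-subtraction; cross-entropy adds the
  dtype tiny to the log argument.
* Empty masks, single pixels and collinear masks raise fit errors;
  coincident landmarks raise geometry errors; unknown states, layers
  and labels raise named lookup errors.
* The truncated-normal sampler redraws within bounds (50 attempts, then
  clips); face sampling redraws wholesale until all anchor points lie
  inside the head silhouette, continuing one rng stream so results stay
  seed-deterministic.

## Known limitations

* The desk-scale (tiny, from-scratch) protocol reaches seed-averaged
  per-class sensitivities in the mid-80s to mid-90s percent range on
  held-out synthetic data; individual seeds fluctuate by several points
  because 110 iterations is a very short optimization budget.
* Saliency localization is resolution-limited: heatmaps are upsampled
  from 8×8 (or 16×16) feature maps, so thresholded mass spreads well
  beyond thin structures like the mouth band. On this benchmark the
  trained classifier's tail-pinch saliency concentrates on the
  eye–mouth front-face region rather than the ear+mouth masks — a
  *normal* eye is discriminative for tail-pinch precisely because the
  brushing eye is deformed — so heatmap mass inside the tail-pinch
  deformed parts exceeds their area fraction but stays far below one
  half, whereas for brushing the deformed parts (ear, jaw, eye) capture
  it by a wide margin. Saliency on synthetic data validates the
  mechanics, not the biology.
* `run_pipeline` re-executes enabled stages; completed stages are
  skipped only by disabling them in the config (no file-hash resume).
* The split stratifies by class, not by animal; real multi-animal data
  would need grouped splitting to avoid identity leakage.
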