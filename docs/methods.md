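# Methods

## The measurement model

The system treats staging of pterygium progression as a geometry problem on
two binary masks.  The cornea is modeled as an ellipse; its transverse
(horizontal) semi-axis in pixels is `RD`, taken as half the longest
horizontal chord of the cornea mask, and the center is the intersection of
the longest horizontal and vertical chords' midpoints.  Removing the
pterygium mask from the cornea mask by pixel-wise XOR leaves the residual
cornea; `MD` is the minimum Euclidean distance from the center to the
residual boundary (foreground pixels with a 4-neighbor background pixel).
Because only the ratio `MD/RD` enters the invasion width

    WP = (d/2) · (1 − MD/RD),

the result is invariant to image scale and needs no pixel calibration —
only the assumed transverse corneal diameter `d`.  The default is
`d = 11.5 mm`, the middle of the anatomical 10.7–12.58 mm range; it can be
overridden per eye when the true diameter has been measured.  The
pterygium area is `π(d/2)²·(A_P/A_C)` with `A_P`, `A_C` pixel areas,
treating the cornea as a circle of diameter `d`.  Staging uses
`WP = 0 / (0, 3) / ≥ 3 mm` with the 3 mm surgery threshold configurable.

Numerical conventions: 0-based (row, col) pixel-center coordinates; `WP`
is zero within 1e-9; only the largest 8-connected component of each mask
is measured; a pterygium mask is intersected with the cornea before the
XOR so `A_P` is by construction the pterygium area *within* the cornea.

**MD mode caveat.**  Taken literally, `MD` is a global minimum over the
residual boundary.  For an uninvaded but eccentric cornea that minimum is
the *vertical* semi-axis, which would report a spurious `WP > 0`.  The
default therefore remains `global_min` (the literal definition), and a
`transverse` mode restricts candidate boundary points to the horizontal
line through the center; the phantom generator defaults to circular
corneas, where the two coincide.  Pipelines that know the pterygium mask is
empty report `MD = RD` directly, since rasterized boundaries otherwise sit
up to half a pixel inside the true circle and would produce `WP ≈ 0.03 mm`
artifacts on normal eyes.

## Ellipse regularization

Network cornea boundaries are jagged; the package fits an ellipse to the
boundary points by the direct least-squares method (smallest algebraic
distance under the constraint `4ac − b² = 1`), in the numerically stable
Halir–Flusser block formulation with centered/scaled coordinates, and
re-rasterizes it.  The fit is exact to ~1e-6 on noise-free samples and
recovers rasterized ellipses to within a pixel; on degenerate input the
pipeline falls back to the raw mask with a warning.

## Segmentation stage

Two architectures are provided.  The cornea stage uses a plain U-Net
(four down-samplings at 512×512 input by default).  The pterygium stage
uses U-Net++ — nested decoder nodes `X[i][j]` receiving all same-level
predecessors plus the up-sampled node below — with one additive attention
gate per up-sampling step of every nested node: the coarser feature map
that is about to be up-sampled is the gating signal `g`; it and the
average-pooled skip concatenation are projected by 1×1 convolutions to an
intermediate width (default half the skip channels), summed, passed
through ReLU, projected to one channel, squashed by a sigmoid into a
weight map α ∈ [0, 1], bilinearly up-sampled, and multiplied onto the skip
features.  Forcing α ≡ 1 reduces the attention network *exactly* to plain
U-Net++ with the same shared weights (a tested identity).  Deep
supervision is not used; the top-level node of the last column feeds a
1×1 prediction head producing a single-channel logit map.  The
probability-to-mask threshold is 0.5.

Losses: the cornea preset trains with numerically stable
binary-cross-entropy-with-logits under RMSprop (lr 1e-5, momentum 0.9,
squared-average decay 0.99, batch 4, weight decay 1e-8, 100 epochs,
checkpoint selection by validation Dice).  The pterygium preset trains
with the combined loss

    loss = 1e-3 · BCE(p, y) − Dice_soft(p, y)

under Adam (lr 1e-3, β 0.9/0.99, batch 16, weight decay 1e-4, 300 epochs,
selection by validation mean-IoU).  The combined loss is negative near
convergence (minimum −1), which surprises users; a `shifted` variant adds
the constant 1 (using the Dice *loss* `1 − Dice`) with identical
gradients.  Soft Dice uses the linear form `(2Σpt + s)/(Σp + Σt + s)` with
smoothing `s = 1` inside training and `s` configurable in the public
function.  Because the pterygium occupies a small fraction of the image,
the output layer's bias is initialized at the training foreground prior's
log-odds by default; without this the Dice term can drive the sigmoid into
its saturated all-background regime early in training, from which
gradients cannot recover.

Preprocessing: the cornea stage applies a per-channel 2–98 percentile
contrast stretch followed by CLAHE (clip limit 0.01, 8×8 tiles) and an
area-interpolation resize to 512×512; the pterygium stage applies the
percentile stretch and resizes to 96×96.  Augmentation applies one
spatial transform (horizontal flip p=0.5, rotation up to ±15°, translation
up to ±5%) identically to image and mask, linear interpolation for the
image and nearest-neighbor for the mask, deterministic per seed.
Validation splits are drawn once per run from the run seed.  Network
pterygium masks are edge-smoothed by morphological opening then closing
with a disk of radius 2 px at the 96×96 prediction scale.

### The autodiff engine

No GPU framework is assumed: `pterymeter.nn` is a small reverse-mode
automatic-differentiation engine over numpy arrays (broadcast arithmetic,
reductions, ReLU/sigmoid/log, channel concatenation, im2col-based
stride-1 convolution, 2×2 max/average pooling, and spatial resampling as
an explicit row-stochastic linear operator, which makes the bilinear
up-sampling adjoint exact).  Convolution gradients are verified against
central finite differences in the test suite.  Models default to float32;
the engine preserves dtypes, so float64 can be used where gradient checks
demand it.

## Synthetic phantoms

The generator emulates the three photograph classes the system ingests: a
bright gray sclera, an elliptical textured iris/cornea disk with a darker
pupil, and an optional pinkish wedge-shaped pterygium entering along the
transverse axis from the left (temporal) or right (nasal) side, plus
additive Gaussian noise (SD 4 intensity units by default).  Masks are
exact by construction (pixel-center inequalities), and truth measurements
are closed-form: the wedge apex sits on the transverse axis at distance
`a·(1−f)` from the center (`f` = invasion fraction), so the apex is the
closest residual-boundary point and `MD = a·(1−f)` exactly, giving
`WP = (d/2)·f` for circular corneas.  The wedge area inside the cornea
decomposes into a triangle plus an elliptical segment with the crossing
abscissa found by bisection, so the truth area ratio needs no
rasterization either.

Phantoms default to circular corneas (`a = b`), matching the observation
that normal eyes measure `RD = MD` exactly only when the fitted ellipse is
near-circular; eccentric phantoms are supported, with the truth `MD`
capped at the vertical semi-axis to mirror the global-minimum definition.
Dataset generation draws the cornea radius as 0.31–0.43 of the image size
(80–110 px at the default 256 px), center jitter ±3% of image size,
invasion fraction 0.1–0.9, wedge half-angle 0.25–0.5 rad,
all from a single seed (spawned per sample, bit-reproducible).

What phantoms do *not* model: specular highlights, eyelids and lashes,
vascular texture of real pterygia, illumination gradients, or annotation
noise.  Passing the recovery tests therefore demonstrates correctness of
the geometry and statistics pipeline and trainability of the networks on
well-contrasted targets — not clinical-grade segmentation accuracy, which
depends on real training data.

## Statistics

All formulas are implemented directly and cross-checked in the tests
against scipy/scikit-learn: Pearson χ² without continuity correction
(p-value from the χ² survival function, `df = (k−1)²` for a square k×k
table), the contingency coefficient `C = √(χ²/(n+χ²))` with its bound
`√((k−1)/k)` (0.8165 at k = 3), and Cohen's kappa in the standard
unweighted form `(Po − Pe)/(1 − Pe)` — the form that reproduces the
published κ = 0.918 from the published crosstab; a linear-weighted variant
(which gives 0.937 on the same table) is available behind a flag.  Binary
diagnostic metrics report `None` rather than 0 when a denominator is
empty.  ROC curves enumerate all score thresholds with "higher WP ⇒
surgery-positive" orientation; AUC is trapezoidal and equals the
Mann–Whitney pair-counting statistic (ties half-credited), a tested exact
identity; the Youden-optimal threshold breaks ties toward the larger
cutoff.  Bland–Altman uses `mean ± 1.96·SD` of paired differences with the
n−1 SD.  Mean-IoU over a dataset is the mean of per-image values.

## Problem sizes used in validation

Phantom recovery runs 60 circular phantoms at 256 px; mask-level
truth-vs-measurement agreement uses 512 px phantoms where rasterization
error is ≈1% of area and ≈0.03 mm of WP.  The network overfitting check
trains the attention-gated U-Net++ (base width 8, depth 3) on eight 96×96
phantoms with fat wedges (~5% foreground) under the pterygium preset,
batch 4, stopping once training Dice reaches 0.92; it converges in roughly
70 epochs.  These sizes are the package's validation defaults and scale up
transparently.

## Known limitations

- The corneal surface is curved; projecting it to a flat ellipse
  underestimates peripheral distances.  No curvature correction is applied.
- `WP` is defined along the transverse axis; pterygia entering far from
  that axis are still measured by the global-minimum `MD`, which may not
  equal the clinically palpated invasion depth.
- The 11.5 mm diameter assumption propagates multiplicatively into `WP`
  and quadratically into area; per-eye diameters should be supplied when
  available.
- Training at clinical scale (hundreds of 512×512 images, hundreds of
  epochs) is outside the intended envelope of the numpy engine; the
  package's training path is meant for method validation and small
  studies.
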