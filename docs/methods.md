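# Methods

## The problem and the data model

Each fly in the archive occupies one line of a 20-line page; its pair of
wings was photographed at 1024 × 1280 and named by volume/page/line/side
(`V20P076L08R`). The biological record carries `vpn` (volume, page,
number), the dissector-measured wing length `wlm` in mm (landmark 1 to
landmark 6; one pixel ≈ 0.007 mm), and counts of missing landmarks per
side. Eleven vein-intersection landmarks, numbered 1–11, define wing
shape; the hatchet cell spans landmarks 7–11. All coordinates in this
package are 0-based (x = column, y = row) in native image space;
model-space coordinates are derived views under the per-axis factors
(W_native/W_model, H_native/H_model). Right wings are mirrored to left
orientation (x → W − 1 − x) before any model sees them.

## Synthetic wing world

The generator exists so that every stage has exact ground truth. A wing
is a fixed skeleton of eight quadratic Bézier "veins", each forced
through three of the 11 template landmarks so that every landmark is a
true intersection of at least two rendered curves. Per wing the template
is perturbed by Gaussian landmark jitter (`shape_sd`, default 0.01 of
the unit frame) — the inter-individual shape variation that gives
Procrustes disparity something to measure — then mapped by a similarity
transform: span 45–65% of canvas width, rotation ±15°, shift ±8% per
axis, plus brightness/contrast variation and Gaussian pixel noise
(SD 0.02). Recorded `wlm` is the true landmark-1→6 distance × 0.007
mm/px plus dissector noise (SD 0.02 mm).

Damage modes: `missing_lm4` / `missing_lm6` place a gross bright
occluder (tape-glare style, radius max(10 px, 10% of span)) over the
landmark and invalidate only that landmark's ground truth;
`torn`/`stained` are benign defects that never invalidate landmarks;
`absent_wing` invalidates all 11. The tier-1 label is 1 exactly for
{missing_lm4, missing_lm6, absent_wing}.

Pages inject misalignments as the photographing slips that motivate the
QC stage: `skipped_image` associates every image name from the error
line onward with the following line's wing (the last line is never
photographed under its own name); `duplicated_image` repeats one wing
under two names and shifts the association one step ahead.

What a green test does *not* establish: the wings are not
photorealistic (no microscope optics, species differences, lamination
artefacts), damage is geometrically simple, and shape variation is
isotropic landmark jitter rather than structured biological covariance.
Results transfer as statements about the pipeline's correctness, not
about accuracy on real wings.

## Models

Because training must run on one CPU, the heads are built on a small
numpy layer stack (3×3 same-padding convolutions via im2col, 2×2 max
pooling, nearest-neighbour upsampling, fully connected layers, ReLU,
Adam, float64 throughout). Ingestion resizes to a square model input
(default 64 px; 224 is valid but slow), replicates grayscale to three
channels and subtracts 0.5 for conditioning.

- **Tier-1 classifier**: three conv/pool blocks, global max pooling
  (the damage cue is a blob that can sit anywhere, so the feature must
  be position-invariant) and a single fully connected unit
  ((feature_dim + 1) parameters) with sigmoid; BCE loss,
  Adam, decision threshold 0.5, checkpoint at minimum validation loss.
  The published protocol (lr 10⁻⁴, 30 epochs, batch 50) is the config
  default; desk-scale tests use the config-exposed knobs (lr 5·10⁻³,
  batch 10, 10 epochs) because 30 minibatch steps cannot move a
  from-scratch network. The affine augmentation is applied on the fly
  to every training image.
- **Regression head**: conv blocks, one extra randomly initialised 3×3
  conv, then a 22-unit output layer; targets are landmark coordinates
  normalised to [0, 1] by the model input size; MSE averaged over
  coordinates; two Adam sessions with lr 10⁻³ then 10⁻⁴, each keeping
  its minimum-validation-loss weights.
- **Segmentation head**: symmetric encoder–decoder emitting 11 logit
  maps; targets are binary disks (pixel k = 1 iff within R of landmark
  k in model space, R default 5 at 224-scale, 3 at 64); loss
  (BCE + dice)/2 with dice ε = 1.0, sigmoid before loss and inference.
  Map → coordinate: unweighted centroid of all pixels ≥ the 7th value
  of the descending pixel multiset (duplicates counted, so a binary
  disk of ≥ 7 pixels selects the whole disk; a constant map
  degenerates to the grid centroid). The rule always produces a point,
  even for an absent landmark — the tier-1 gate exists to keep such
  images out.
- **Baseline**: the per-landmark mean of the training coordinates.

Augmentation samples scale and per-axis shift uniformly from [−5%, +5%]
and rotation from [−22°, +22°], composed as rotation about the image
centre, then scale, then translation (a declared convention; a single
sampled similarity transform would differ only in parameter
interpretation). Pixels are warped bilinearly with border-median fill;
coordinates get the exact affine map; samples whose valid landmarks
leave the frame are resampled once, then skipped.

## Evaluation and shape bias

Errors are per-(image, landmark) Euclidean distances in native pixels;
summaries report MAE, RMSE, and — because the distributions are skewed —
the empirical 2.5/50/97.5 percentiles (linear interpolation between
order statistics) rather than normal-theory intervals of the mean.

Shape bias: generalized Procrustes alignment centres each shape, scales
it to unit centroid size and iteratively rotates it onto the evolving
mean (no reflection — wings are chirality-fixed after flipping;
convergence 10⁻⁸ on mean-shape change, ≤ 100 iterations). Disparity is
the root-sum-of-squares distance from the mean shape; ground-truth
shapes are aligned by default (predicted shapes are supported). OLS of
per-image mean error on disparity is fitted after removing the union of
points beyond 2 SD of the mean on either variable, reporting R² before
and after; a near-zero slope/R² is the desired "no shape bias" outcome.

## Alignment QC

Per page, the R² (squared Pearson correlation) between recorded `wlm`
and the predicted landmark-1→6 length flags misalignment when below 0.1.
Pages with fewer than 3 usable lines or zero variance are surfaced as
degenerate for manual review, never silently passed. A known
statistical limit, inherent to the rule: for a page of n ≤ 20 lines a
one-step misalignment leaves the pairs a shifted permutation of iid
lengths, so the page R² follows the null Beta(1/2, (n−2)/2), which
exceeds 0.1 with probability ≈ 0.17–0.20 at n = 18–20. Per-page
detection of single-slip pages therefore saturates near 80–85% no
matter how accurate the predictions; pages with errors late on the page
are missed far more often. Corrections are machine-readable actions
(shift_association, remove_line, remove_page); applying the log to
identity associations reproduces the corrected record→image mapping,
and on synthetic pages with known truth the corrected page returns to
R² = 1 at zero noise.

The global measured-vs-predicted regression uses a flat prediction band
(fit ± 1.96 × residual SE, not leverage-adjusted) to flag outliers;
hatchet-cell-measured records are excluded via an explicit flag since
no rule for identifying them from the records alone is defined.
Sampling margins use the normal approximation with finite-population
correction, z·√(p̂(1−p̂)/n)·√((N−n)/(N−1)).

## Numerical and design choices

- Tiny-network input 64 px (divisible by 8); coordinate contracts are
  native-space, so resolution only affects localisation sharpness.
- MaxPool splits gradient equally among tied maxima (ties are rare with
  float activations and this keeps the backward pass exact).
- Tier-2 batch size 16; dice ε = 1.0; disk radius exposed in config
  (deliberately not optimised, as is the top-7 inference parameter).
- Splits are 60:20:20, stratified by completeness label for tier 1;
  tier 2 trains only on complete wings.
- Undefined bootstrap metrics (e.g. precision in a resample with no
  predicted positives) are excluded from that metric's percentile
  computation rather than imputed.
- Degenerate inference inputs are documented behaviour, not errors: a
  constant activation map yields the image centroid; a zeroed
  regression head predicts the coordinate origin.

## Known limitations

The three named ImageNet backbones are interface placeholders without a
deep-learning runtime; the numpy stack is single-threaded and meant for
desk-scale runs, not deployment-scale inference; the synthetic world's
simplifications above bound what the tests can claim; and the page-QC
detection ceiling described earlier is a property of the single-QID
R² rule itself.
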