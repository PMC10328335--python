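# wingmarks

Morphometric studies of tsetse flies (*Glossina* spp.) use the relative
positions of 11 wing-vein intersection points — anatomical landmarks — to
measure wing size and shape, a cheap phenotypic proxy for population
structure that matters for trypanosomiasis control. Archived collections
hold tens of thousands of wing photographs taped to dissection record
sheets, far too many to landmark by hand. `wingmarks` implements the full
semi-automated workflow for turning such an archive into a
morphometrics-ready landmark dataset, and ships a synthetic wing
generator so every stage is testable end to end without the real images.

The workflow has two tiers plus quality control:

1. **Tier 1 — completeness gate.** A CNN scores each (left-oriented)
   image with a sigmoid output; wings missing landmark 4 or 6 (the
   dominant damage categories) are rejected. Trained with binary
   cross-entropy and Adam, checkpointing at the minimum validation loss;
   test metrics (sensitivity, specificity, precision, F1, accuracy)
   carry 95% percentile-bootstrap confidence intervals.
2. **Tier 2 — landmark localisation**, two interchangeable heads:
   - *Coordinate regression*: 22 outputs, the normalised (x, y) of the
     11 landmarks, trained with MSE over two Adam sessions
     (lr 10⁻³ → 10⁻⁴).
   - *Disk segmentation*: 11 activation maps trained against binary
     disk targets of radius R (pixels within distance R of landmark k)
     using the loss (BCE + dice)/2. A map becomes a coordinate as the
     unweighted centroid of all pixels ≥ the 7th-highest pixel value.
   Both are compared against a constant mean-location baseline, with
   errors reported as Euclidean pixel distances (MAE, RMSE and
   2.5/50/97.5 percentiles) in native 1024 × 1280 space.
3. **Shape-bias check.** Generalized Procrustes alignment gives each
   wing a disparity (distance from the mean shape after removing
   translation, scale and rotation); OLS of per-image mean pixel error
   on disparity — after trimming 2-SD outliers on both variables —
   quantifies whether the model favours particular shapes.
4. **Alignment QC.** The dissector-measured wing length *wlm*
   (landmark 1→6 distance × 0.007 mm/px) is the single quasi-identifier
   linking records to images. A duplicated or skipped photograph shifts
   every later image on a 20-line page, collapsing the page-level R²
   between *wlm* and predicted length; pages with R² < 0.1 are flagged,
   corrected via a machine-readable log, and a global
   measured-vs-predicted regression flags residual outliers. Sampling
   margins use z·√(p̂(1−p̂)/n)·√((N−n)/(N−1)) (finite-population
   correction).

The neural heads run on a small self-contained numpy layer stack
(`wingmarks.nn`) so the whole protocol trains on one CPU; the named
ImageNet backbones are interface placeholders that raise an informative
error when no deep-learning runtime is available.

## Worked example

```python
import numpy as np
from wingmarks import synthetic, evaluation
from wingmarks.landmarks import (RegressionConfig, build_regression_net,
                                 train_regression, predict_regression,
                                 baseline_mean_location)
from wingmarks.pipeline import split_indices

rng = np.random.default_rng(11)
wings = [synthetic.generate_wing(synthetic.sample_spec(rng, canvas=(128, 160)))
         for _ in range(300)]
pairs = [(img, lms) for img, lms, _ in wings]
rng = np.random.default_rng(0)
tr, va, te = split_indices(300, (0.6, 0.2, 0.2), rng)
cfg = RegressionConfig(input_size=64, session_epochs=(30, 15))
model = build_regression_net(cfg, rng)
train_regression(model, [pairs[i] for i in tr], [pairs[i] for i in va], cfg, rng)
preds = [predict_regression(model, pairs[i][0], 64) for i in te]
truths = [pairs[i][1] for i in te]
s = evaluation.distance_errors(preds, truths)
b = baseline_mean_location([pairs[i][1] for i in tr])
sb = evaluation.distance_errors([b.predict() for _ in te], truths)
print(f"model MAE {s.mae:.2f}px  baseline MAE {sb.mae:.2f}px")
```

prints (≈ 90 s on one CPU):

```
model MAE 7.79px  baseline MAE 9.78px
```

i.e. the tiny regression head, trained on 180 synthetic wings at a
reduced 128 × 160 canvas, localises landmarks with a mean error of about
8 px, clearly below the 9.8 px of the constant mean-location baseline —
the baseline is only that good because synthetic wings vary moderately
in position and rotation.

A command-line interface wires the same stages
(`wingmarks simulate | train-classifier | train-landmarks | predict |
evaluate | shape-bias | align-qc | run-all`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computation from scratch at desk scale: the
finite-population sampling margins, tier-1 training with bootstrap
metrics, tier-2 regression training against the baseline, the
Procrustes shape-bias regression, and misalignment QC on a synthetic
100-page volume with 2% injected skipped-image errors. The computed
summary is printed to stdout and the results object is written to
`--out`.
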