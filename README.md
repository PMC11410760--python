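# pretextnet

Modality-specific pretext learning for grayscale radiograph classification,
end to end and dependency-light (pure NumPy/SciPy networks — no GPU or
deep-learning framework required):

1. **phantom** — synthetic chest-like grayscale phantoms (lung-field
   ellipses, rib banding, optional focal opacities) with labeled cohorts and
   a leakage-free patient-level 70/10/20 split.
2. **degrade** — stochastic Gaussian noise (variance factors
   0.02–0.1) and Gaussian blur (kernel sizes 3–9, auto sigma) producing
   paired restoration datasets.
3. **sharp_unet / pretext** — a VGG-16 encoder–decoder restorer with fixed
   depth-wise *sharpening* skip connections
   (`[[0,-1,0],[-1,5,-1],[0,-1,0]]`, zero learnable parameters), trained
   with SSIM loss, Adam, reduce-on-plateau (0.5× after 10 stale epochs,
   floor 1e-6) and best-validation checkpointing.
4. **transfer** — the restorer encoder truncated at its deepest convolution
   + GAP + 2-node softmax head, fine-tuned with SGD under the same plateau
   regimen; random-init and external-checkpoint baselines.
5. **ensembles** — simple averaging, simplex-constrained SLSQP weighted
   averaging (validation log-loss objective), and a learnable
   attention-fuzzy combiner: per-member attention weights over concatenated
   GAP features, combined member logits scaled by a trainable fuzziness
   scalar before the softmax; member backbones frozen (checksum-verified).
6. **iqa / clf_metrics / stats** — PSNR, SSIM, HaarPSI, MSE, MAE;
   balanced accuracy, sensitivity, specificity, F-score, MCC, Kappa,
   Youden's index at threshold 0.5; pairwise sensitivity Z-tests with
   standard errors recovered from Wilson 95% CI widths.
7. **scorecam** — gradient-free Score-CAM maps from the deepest
   convolutional layer, extreme-point bounding boxes, and IoU against
   ground-truth boxes.

## CLI

```bash
pretextnet run-all --config config.yaml --workdir runs/exp1
pretextnet degrade --mode noise --in images/ --out noisy/ --seed 1
pretextnet train-pretext --mode deblur --clean clean/ --degraded blurred/ --out restorer.npz
pretextnet score-restoration --gt clean/ --pred restored/ --out report.csv
pretextnet evaluate --pred predictions.csv --out metrics.csv
pretextnet compare --metrics metrics.csv --out comparisons.csv
pretextnet explain --model classifier.npz --images test/ --gt-boxes boxes.csv --out overlays/
```

`run-all` executes the stage graph phantom → degrade → pretext → transfer →
ensembles → metrics → stats (+ scorecam), records a JSON manifest with
per-stage seeds, parameter echoes and artifact hashes, skips up-to-date
stages on re-run, and re-executes exactly the downstream stages when one
stage's configuration changes. Example config:

```yaml
seed: 5
image_size: [64, 64]
stages:
  phantom: {n: 200, prevalence: 0.5}
  pretext: {max_epochs: 30, batch_size: 16, width_multiplier: 0.125}
  transfer: {max_epochs: 10, batch_size: 16}
```

## Conventions

Canonical intensities are `[0,1]` floats (0–255 only at file boundaries);
arrays are row-major and 0-based; bounding boxes are inclusive; save-time
quantization rounds half away from zero. Every stochastic operation's seed
derives from a single global seed and a stage name.
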