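# Methods

This note describes what `collascore` implements, the modelling assumptions
behind it, every user-facing parameter with its default, what the synthetic
phantom generator does and does not emulate, the numerical choices made for
single-CPU execution, and the known limitations.

## 1. Problem and scoring convention

Collateral status on acute-stroke CTA is graded by comparing contrast
filling of the occluded middle-cerebral-artery (MCA) territory with the
contralateral, healthy hemisphere. The 4-level scale maps the filled
fraction `f` of the territory onto a score:

| filling fraction `f` | score | meaning |
|---|---|---|
| `f = 0` | 0 | no collateral filling |
| `0 < f < 0.5` | 1 | less than half filled |
| `0.5 <= f < 1` | 2 | more than half filled |
| `f = 1` | 3 | complete filling |

Endpoint comparisons use a tolerance of `1e-6`. The dichotomized score
groups {0,1} as *poor* (0) and {2,3} as *good* (1); "positive" always means
good collaterals.

## 2. Preprocessing

Input volumes are assumed to be registered to a ~1 mm isotropic atlas space
**outside** this package (e.g. ANTs; see `preprocess.registration_hook`).
NIfTI files are canonicalized to RAS on load, so the first array axis is
always left–right.

1. **Orientation** — `orient_affected_right` flips the volume about the
   mid-sagittal plane so the affected hemisphere sits at high x-index.
2. **Split + mirror** — `split_and_mirror` cuts the volume into two halves
   of width `ceil(W/2) + overlap` and mirrors the healthy half, giving
   voxelwise correspondence between the two branch inputs. The overlap
   supplies mid-line context; the default 10 voxels refers to the ~180-voxel
   clinical grid and `scale_overlap` shrinks it proportionally for smaller
   grids (e.g. 4 voxels at width 64).
3. **Normalization** — intensities are windowed from [35, 165] HU linearly
   onto [−1, 1] with clipping; contrast-filled vessels saturate at +1.

## 3. Network

`SiameseCollateralNet` applies one weight-shared volumetric residual
backbone (VoxResNet-style, adapted) to both halves:

- **Backbone** (`BackboneConfig`): stem convolutions, stride-2
  downsampling, pre-activation residual blocks
  (IN → ReLU → conv3×3×3, twice, plus identity), and, when two resolution
  levels are configured, a deeper ¼-resolution stream fused back by
  nearest-neighbour upsampling and addition. Feature maps live at ½
  resolution. Instance normalization replaces batch normalization because
  training uses batch size 1; `eps = 1e-5`.
- **Masked global average pooling** — the feature map is averaged over the
  MCA-territory mask resampled to feature resolution by 2×2×2 *any*
  pooling (a thin territory never disappears). Voxels outside the mask
  contribute to neither numerator nor denominator.
- **Head** — the two pooled F-vectors are concatenated (2F) and mapped by a
  single linear layer to 4 logits; softmax gives the score distribution.
  `p23 = p2 + p3` is the dichotomized probability.
- **Whole-brain ablation arm** — the same backbone applied once to the
  unsplit volume, pooled over the bilateral mask, with an F-wide head. The
  backbone parameter count is identical; only the head differs (4·F fewer
  weights).

**Class activation maps.** Because the head is linear and pooling is a
masked mean, applying the head per voxel yields per-class evidence maps
whose masked spatial mean equals the corresponding logit exactly (verified
to 1e−4 in tests; exact up to float round-off). For the Siamese model the
map splits into affected- and healthy-hemisphere contributions. Ensembles
average CAMs voxelwise, the linear pre-softmax analogue of probability
averaging.

Backbone configurations:

| config | features | blocks | full-res stem | intended use |
|---|---|---|---|---|
| `BackboneConfig()` | 28 | (2, 2) | yes | clinical-scale volumes |
| `reduced_backbone(8)` | 8 | (0, 2) | no | phantom-scale CPU runs |

The reduced layout places its residual blocks at ¼ resolution behind a
single stride-2 stem convolution, which cuts CPU time by roughly an order
of magnitude while keeping the two-level residual structure.

## 4. Training

`TrainingConfig` defaults (full-model recipe):

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.3 | loss mix: `(1−α)·BCE(p23) + α·CCE(4-class)` |
| `smoothing` | 0.2 | label smoothing `ys = (1−s)·y + s/K`, K = 4 |
| `epochs` | 100 | training length `T` |
| `max_lr` | 2e-4 | peak of the warm-up cosine schedule |
| `scheduler` | `warmup_cosine` | linear ramp to `max_lr` at T/2, cosine to 0 at T |
| `batch_size` | 1 | one volume per step (instance norm assumption) |
| `seeds` | (0, 1, 2) | ensemble member seeds |
| `folds` | 5 | stratified cross-validation folds |
| `cosine_lr0`, `cosine_epochs` | 5e-4, 200 | `cosine_decay` ablation schedule |
| `overlap` | 10 | hemisphere overlap passed to the splitter |
| `whole_brain` | False | non-Siamese ablation arm |

- **Hybrid loss.** Binary cross-entropy on the dichotomized probability
  plus categorical cross-entropy on the 4-class distribution, weighted
  (1−α)/α. Probabilities are clamped to `[1e-7, 1−1e-7]`. The gradient
  with respect to the logits is analytic
  (`hybrid_loss_grad`), verified against finite differences.
- **Label smoothing** uses K = 4 (the number of classes); the smoothed
  dichotomized target is `ys[2] + ys[3]`.
- **Balanced epochs.** Each epoch draws `m = round(N/4)` samples per class —
  minority classes with replacement, majority classes without — then
  shuffles. On a 12/82/123/61 cohort this yields 70 per class.
- **Augmentation** is applied to the *full* aligned volume before
  splitting, so the two halves stay in correspondence. One random transform
  per draw: rotations up to ±20° in all three planes, per-axis scaling
  ±10%, translations up to 10 in-plane / 3 slice voxels, and an elastic
  B-spline free-form deformation (control spacing 20 voxels, perturbations
  up to 10 voxels). Voxel-valued magnitudes scale with grid width
  (`scaled_for_width`). The mask is warped with the same field using
  nearest-neighbour interpolation.
- **Optimizer** is Adam (β = 0.9/0.999, eps 1e-8) with the scheduled
  learning rate evaluated at the fractional epoch of every step.
- **Model selection.** `cross_validate` runs stratified k-fold training and
  returns the epoch maximizing mean validation accuracy; `train_ensemble`
  trains one model per seed, and predictions/CAMs are averaged.

## 5. Calibration and metrics

`calibrate_threshold` sweeps the unique predicted `p23` values (plus 0.5)
in descending order and returns the **largest** threshold whose sensitivity
for good collaterals reaches the target (default 0.81) — the most specific
operating point still matching the reference sensitivity. Ties
`p23 == θ` count as positive. The final 4-level score is forced to agree
with the dichotomized decision: `argmax(p2, p3) + 2` above threshold,
`argmax(p0, p1)` below; argmax ties break to the lower class.

`compute_metrics` reports the 4×4 confusion matrix (rows = reference),
multiclass and dichotomized accuracy, sensitivity, specificity, the ROC on
`p23` and its AUC (scikit-learn), with optional per-group breakdowns.
`quantitative_score` is the probability-weighted expected score
`Σ c·p_c ∈ [0, 3]`.

## 6. Phantom generator: scope

`generate_phantom` emulates exactly the property the classifier must
read out — *relative* vascularization of mirrored territories:

- an ellipsoidal "territory" (~30% of the hemisphere volume, shifted
  laterally) placed mirror-symmetrically in both hemispheres;
- bright tubes (radius 1–2 voxels, intensity 300 HU on 40 HU tissue) drawn
  in the healthy hemisphere until 25% of the territory volume is vessel;
- the affected hemisphere receives the mirrored tube set trimmed to
  **exactly** `round(f · N_healthy)` voxels, so the realized
  vascularized-volume ratio equals the requested `f` up to voxel
  quantization (measured error < 1/N);
- Gaussian noise (σ = 5 HU) on top.

It does **not** emulate: realistic vascular trees or hemodynamics, skull
and soft tissue, partial-volume effects, registration error, pathology
other than reduced filling, scanner artifacts, or anatomical asymmetry.
Class bands for dataset sampling keep `f` away from the decision
boundaries (1: `f ∈ [0.02, 0.48]`, 2: `f ∈ [0.52, 0.98]`) so voxel
quantization cannot flip a label.

## 7. Numerical choices

- **NumPy engine.** All layers (3D convolution, instance norm, ReLU,
  nearest upsampling, linear) are implemented in float32 NumPy with
  explicit backward passes, verified against central finite differences.
  Convolution uses 27 strided-slice GEMMs per layer rather than an im2col
  buffer, which is both faster and lighter in memory at these sizes.
- **First-layer gradient skipped.** The stem convolution never needs a
  gradient with respect to its input; skipping it saves a full backward
  convolution per step.
- **Elastic-field degree.** The free-form deformation is evaluated with
  degree-1 (linear) interpolation of the control grid by default
  (`bspline_degree = 1`); cubic evaluation triples augmentation cost on
  CPU without measurable benefit at phantom scale.
- **Seeds.** Every stage seed derives from the master seed through
  `numpy.random.SeedSequence([master, stage])`, reduced modulo 2³¹−1; all
  artifacts are reproducible from `RunConfig` alone.

## 8. Limitations

- The engine targets desk-scale experiments: single CPU, batch size 1; no
  GPU path, no multi-threaded convolutions beyond BLAS.
- Atlas registration, skull stripping and the MCA-territory atlas itself
  are out of scope; the package consumes pre-aligned volumes and masks.
- Phantom results demonstrate that the pipeline recovers relative-filling
  labels from images; they say nothing about clinical performance.
- The full 28-feature configuration is provided and functional but slow on
  CPU; quantitative claims in this repository are made with the reduced
  backbone.
- Binary masks only; probabilistic territory maps are not supported.
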