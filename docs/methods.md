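# Methods

`relmap3d` re-implements a comprehensible-CNN pipeline for dementia detection
on 3D gray-matter density maps: covariate residualization, a compact 3D
convolutional classifier, layer-wise relevance propagation (LRP), relevance
analytics, and ROC-based evaluation. Real dementia cohorts are
access-restricted, so the package ships a synthetic-cohort generator with the
statistical structure the pipeline assumes, and every result below is
computed on such cohorts. This note documents the models, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
setting does and does not establish.

## Covariate residualization

Voxel intensities in modulated gray-matter maps carry nuisance effects of
age, sex, total intracranial volume (TIV) and scanner field strength (FS).
For each voxel *i* an ordinary-least-squares model

    vx_ij = b_i0 + b_i1 age_j + b_i2 sex_j + b_i3 TIV_j + b_i4 FS_j + e_ij

is fitted **on healthy controls only** and its prediction subtracted from
every subject's map (fit on controls, apply to all), so disease-related
deviations remain in the residuals. The same code path residualizes scalar
features (hippocampus volume). Implementation notes:

* The solve uses a pseudo-inverse with relative rank tolerance 1e-10, so
  zero-variance features (e.g. empty background voxels) get zero slopes and
  residual = value − mean instead of a failure.
* Covariates enter in raw units (years, ml, 0/1 codes). Whether they are
  standardized first is immaterial for the residuals; raw units keep the
  coefficients interpretable (density per year, per ml).
* A rank-deficient design (constant covariate, collinearity) is an error
  naming the offending column; silent dropping would corrupt coefficients.

## The classifier

Three convolution blocks (five 3x3x3 filters, ReLU, 2x2x2 max pooling, batch
normalization), flatten, then three dropout(10%) + dense layers of 64, 32 and
2 units, ReLU on the hidden layers, softmax output; the last two dense layers
carry an L2 penalty (default strength 0.01, configurable — no reference value
exists). Two conventions are pinned down by the published ~700k parameter
count at the 100x100x120 input: convolutions preserve spatial size
("same" padding) and pooling floor-divides odd extents (100 -> 50 -> 25 -> 12).
With those, the trainable count is 694,940 (conv 140+680+680, batch-norm 30,
dense 691,264+2,080+66), which rounds to 700,000; unpadded convolutions would
give ~419k and contradict the published count. Dropout precedes each dense
layer; batch normalization follows pooling inside each block.

The layers are implemented directly on numpy with compiled (numba) kernels
for the 3D convolutions and pooling. This keeps every activation, weight and
pooling winner exposed to the relevance engine, which needs them; it also
means the package has no deep-learning-framework dependency. Weight
initialization is normalized-variance (Glorot) uniform with a fixed seed;
batch-norm uses eps 1e-3 and running-statistics momentum 0.9 (the shorter
memory suits the small step counts of desk-scale runs); Adam uses
beta1 0.9, beta2 0.999, eps 1e-7.

### Training protocol

Binary classification of controls versus the combined MCI+AD group, with
class weights 0.5·n/n_i, categorical cross-entropy, Adam at learning rate
1e-4, batch size 20. Cross-validation is stratified 10-fold **on the
three-class diagnosis** so every test partition mirrors the cohort's CN/MCI/AD
composition. Per fold, the epoch with the best test balanced accuracy is
kept (ties: lower test loss, then the earlier epoch). Defaults are 10 epochs
for residualized inputs and 20 for raw inputs in cross-validation; 4 and 8
respectively for final whole-sample training without checkpointing.

### Augmentation

The reference protocol enlarges each training epoch 14-fold:
{identity, left/right flip} x {no shift, +/-10 voxels along each single axis},
with vacated voxels zero-filled. `augment_variants` implements exactly these
14 variants. The factor 14 = 2 x 7 rules out combined-axis or intermediate
translations. The flip mirrors grid axis 0 (the sagittal L/R axis under this
package's axis convention; configurable).

`TrainConfig.augment` has three modes. `"full"` is the 14-variant protocol
and the default. `"flip"` keeps only the L/R flip (2x stream): the +/-10-voxel
translations are calibrated to the 100x100x120 grid, and on the reduced
40x40x48 demo grid they would displace the phantom by a quarter of the field
of view — a different and much harsher perturbation than in the full-size
setting — so reduced-grid runs use the grid-size-independent flip only.
`"none"` disables augmentation. The end-to-end synthetic validation uses
`"flip"`.

## The LRP engine

Relevance propagation starts from the **pre-softmax score of the target
class** and walks the layers backward:

* **Convolutions: alpha=1/beta=0 rule.** Each output neuron's relevance is
  shared among its inputs in proportion to their positive contributions
  a_j w_jk^+ / sum_j' a_j' w_j'k^+. Implemented in the positive-contribution
  form (a_j w_jk)^+ = a+ w+ + a− w−, which equals the formula above for
  non-negative (post-ReLU) activations and extends it to the signed
  activations that occur after batch normalization and in residualized
  inputs while keeping alpha1/beta0 maps sign-consistent.
* **Dense layers: epsilon rule** with eps = 1e-10 and sign(0) := +1:
  R_j = sum_k a_j w_jk / (z_k + eps·sign(z_k)) R_k, z_k the pre-activation
  including bias. The bias and epsilon absorb a (small) share of relevance.
* **Max pooling:** winner-take-all — each window's relevance is routed to the
  window's maximal input, ties to the lowest linear in-window index,
  mirroring the forward pass winner exactly.
* **Batch normalization** at inference is a per-channel 1:1 affine map;
  applying the propagation rule to a 1:1 connection returns the incoming
  relevance unchanged, so it propagates as identity. An exact fold of frozen
  batch norm into the *following* affine layer is provided for verification
  (`fold_batchnorm_into_conv/dense`); the fold across 'same'-padding borders
  is exact one kernel radius inside the grid.
* **Dropout** is identity at inference; **ReLU** is handled implicitly since
  each affine layer's cached input is already post-ReLU.

Biases are excluded from the alpha/beta denominator, so each convolutional
step conserves relevance exactly except for output neurons whose positive
denominator is zero — their relevance is dropped, never redistributed
(keeping sign consistency); inclusion of positive bias parts in the
denominator is available as an option. Per-layer relevance totals are
recorded in every map, and `conservation_report` decomposes the balance
exactly: start = map sum + convolutional zero-denominator drops +
dense-layer bias/epsilon absorption. The drops have a concrete anatomy-free
origin in this package's phantoms: a trained network produces constant
bias/batch-norm-driven activations over the exactly-zero image background,
and any relevance credited to those constants has no input voxel to land on.
That share belongs to the model's internal offsets, not to the image, and is
reported rather than hidden. The *unaccounted* imbalance — the dense-layer
absorption — stays well below 1% of the starting score at the reference
training protocol. Conservation ratios are quoted against the cohort's
median |starting score|, since a ratio against an individual near-zero logit
is uninformative.

## Relevance analytics

* **Region sums**: total relevance inside an atlas mask (hippocampus
  relevance is the validation anchor).
* **Region volume**: sum of modulated density x voxel volume (1.5^3 mm^3 at
  the default 1.5 mm isotropic grid) / 1000, in ml.
* **Clusters**: connected components of the supra-threshold voxel set
  (>= threshold), face adjacency (6-connectivity) by default with
  26-connectivity available, filtered by minimum size; per-cluster size,
  volume, peak and peak location are reported, plus the pre-filter size
  histogram. Display thresholds (e.g. 0.2) refer to maps normalized by the
  cohort's 99.5th-percentile absolute relevance (`normalize_map`).
* **Per-slice profiles**: separate positive and negative relevance totals per
  sagittal/coronal/axial slice (the viewer's navigation guides).
* **Occlusion sensitivity**: a cube of 20 voxels (= 30 mm at 1.5 mm voxels)
  slides across the grid on a stride lattice (default stride 4; cubes are
  kept fully inside the grid to avoid edge artifacts); voxels inside the cube
  are multiplied by 0.5 (50% simulated gray-matter loss), and the model's
  disease probability — and optionally the total map relevance — is recorded
  per position. For models trained on residuals, the occlusion is applied to
  the gray-matter map and the residual input recomputed (the `preprocess`
  hook): attenuating a near-zero residual directly would not emulate tissue
  loss.

## Evaluation

AUC is the Mann-Whitney probability that a random positive outscores a random
negative (ties count 1/2). The operating threshold maximizes the Youden index
J = sensitivity + specificity − 1 over midpoints of adjacent sorted unique
scores; a subject is positive at score >= threshold; ties on J resolve to the
lowest threshold. (Maximizing J is equivalent to maximizing balanced
accuracy.) The hippocampus-volume baseline classifier residualizes the
volumes, flips their sign (lower volume = higher risk), fits the Youden
threshold on the training partition and applies it unchanged to the test
partition, using the same fold splits as the CNN so the comparison is paired.
Relevance-map validity is quantified as the Pearson correlation between
per-subject hippocampus relevance and residualized hippocampus volume,
reported per model and as the median across models; on trained models this
correlation is strongly negative (more atrophy, more disease relevance).

## Synthetic cohorts

The generator emulates exactly the statistical structure the pipeline
assumes:

* **Template**: a smooth "brain" — an ellipsoid (semi-axes 0.42 x grid) at
  base density 0.8, Gaussian-smoothed (sigma 1.5 voxels), zero outside.
* **Atlas**: non-overlapping ellipsoid/box regions; a `hippocampus` region is
  mandatory, plus `temporal` and `parietal` regions in the default atlas.
* **Controls**: template + sum of per-covariate slopes x covariates +
  Gaussian noise, applied on the brain support, clipped at 0. Default slopes:
  age −0.003/yr, sex −0.02, TIV +1e-4/ml, FS +0.01; noise sd 0.05 — the
  covariate effects are of the order of a few percent of tissue density per
  decade of age, and the voxel noise is modest, as in smoothed modulated maps.
* **Covariates**: age ~ U(60, 85) yr, sex ~ Bernoulli(0.5),
  TIV ~ N(1450, 130) ml, field strength ~ Bernoulli(0.7) (most scans 3T).
* **Patients**: multiplicative intensity attenuation inside designated
  atrophy regions — hippocampus by default — with MCI at half the AD
  fraction (MCI is intermediate). Default AD attenuation 0.4.
* **Determinism**: one cohort seed fans out to covariate and per-subject
  noise streams; identical (spec, seed) gives byte-identical cohorts.

The demo/validation conditions are 200 subjects (100 CN / 50 MCI / 50 AD) on
a 40x40x48 grid at 1.5 mm — sized so that cross-validated CNN training,
relevance mapping and occlusion scanning complete in minutes on one CPU; the
full 100x100x120 grid is supported throughout (the parameter-count and
geometry checks run at full size).

What the phantom does **not** model: anatomy (gyri, tissue boundaries,
asymmetry), spatially graded atrophy within a region, registration error,
scanner artifacts, site effects beyond a binary field-strength covariate, or
label noise. Consequently, passing synthetic tests shows that the pipeline's
machinery is correct and self-consistent — residualization recovers planted
covariate effects, the classifier detects planted atrophy, relevance
concentrates on the truly informative region, occlusion confirms it — not
that the classifier would reach any particular accuracy on clinical data.

## Numerical and degenerate-input conventions

* Training arithmetic is float32; relevance propagation is float64.
* Zero-variance voxels: slopes 0, residual = value − mean.
* LRP zero-denominator columns drop their relevance; epsilon sign(0) := +1.
* Pooling ties: lowest linear in-window index, identical in forward,
  backward and relevance routing.
* Volumes must be finite, 3D, isotropic (non-isotropic files load with a
  warning, keeping the smallest zoom).
* All randomness flows through seeded numpy generators; cross-validation
  fold seeds derive from the training seed plus the fold index, and the
  pipeline derives per-stage seeds from one global seed.

## Known limitations

* CPU-bound training: the full 100x100x120 protocol with 14x augmentation is
  supported but slow on one core; desk-scale validation uses the reduced
  grid.
* The epsilon rule lets trained dense-layer biases absorb relevance, so
  conservation degrades slowly with very long training; at the reference
  protocol's epoch counts the end-to-end deficit stays well under 1%.
* Only the two propagation rules actually used (alpha1/beta0 composite with
  epsilon on dense layers) are implemented; other attribution methods are out
  of scope.
* The interactive viewer itself is out of scope; its backend computations
  (clusters, profiles, lookups, normalization) are the `analysis` module.
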