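# Methods

## Problem and data model

The package targets screening for Alzheimer's disease (AD) from eye
movements recorded during a visual-paired-comparison (VPC) task: a
participant freely views a set of V = 12 scene images twice (5 s per
viewing, gaze sampled at 120 Hz on a 1920x1080 display); between the two
viewings one object per image is added or removed, and the changed region
is the image's region of interest (RoI). Healthy controls (HC) show a
novelty preference — extra looking at the RoI on the second viewing —
while patients (PwAD) concentrate gaze centrally and largely ignore the
change. The classifier consumes only the spatial distribution of gaze: each
(image, viewing) is reduced to a fixation heatmap, and a subject is the
ordered stack of V heatmap pairs.

## Fixation heatmaps

Each on-screen gaze sample (x, y) increments grid cell
(floor(y/45), floor(x/60)) of a 24 x 32 count grid (cells cover 60 x 45 px;
the anisotropy is implied by mapping 1920 x 1080 onto 32 x 24). The count
grid is smoothed with a sampled Gaussian kernel (sigma = 1.0 cells by
default, truncated at 4 sigma, reflective boundary — mass-preserving before
normalization) and scaled so its maximum is 1, matching the bounded
(sigmoid) output of the reconstruction decoder. Sum-to-one normalization is
available as an option. Whether smoothing should precede or follow the
binning is underdetermined at this resolution; the package bins first and
exposes sigma.

Fixation identification defaults to "every valid sample is a fixation
point": at 120 Hz the raw-sample overlay is the fixation density up to the
smoothing scale. A dispersion-threshold (I-DT) mode (50 px dispersion,
100 ms minimum duration) is available for sensitivity analysis. Rows
flagged invalid or off screen are dropped and counted, never imputed; a
subject missing any of the V x 2 recordings is excluded outright, because
the multi-view fusion assumes a complete view set.

## The nested autoencoder

Let x_1, x_2 in [0,1]^{24x32} be the two heatmaps of one image.

**Inner autoencoder** (parameters shared across images). Encoder: the pair
enters as 2 channels; conv(2->8, 3x3, stride 2) -> conv(8->16, 3x3,
stride 2) -> conv(16->32, 3x3) with ReLU, then a dense layer to
z in R^64. Decoder: the mirror image with transposed convolutions and a
sigmoid output, reconstructing both channels. Loss:

    L_inner = 1/2 * sum_{v=1,2} || x_v - x^hat_v ||_F^2.

**Outer autoencoder** (parameters shared across views). A linear encoder
maps each view latent z^v to z~^v in R^32. A weight-adaptive fusion layer
with learnable logits beta_m in R^V forms the subject-level common
representation

    Z = sum_v softmax(beta_m)_v * z~^v,

and a two-layer decoder (32 -> 128 -> V x 64) maps Z back to one
reconstruction z^hat_v per view:

    L_outer = 1/2 * ( sum_v || z^v - z^hat_v ||_F^2
                      + || Z - sum_v w_v z~^v ||_F^2 ).

With Z defined as exactly the fused sum the consistency term is identically
zero; it is retained in the standalone loss function, which accepts any Z.
The first term is a reconstruction error; an alternative reading that
compares z^v with z~^v directly only type-checks when the outer encoder
preserves dimension and is available in the standalone helper as
`first_term="latent"`. Passing beta_m through a softmax (rather than using
it unconstrained) prevents a scale degeneracy between the fusion weights
and the encoder.

**Classifier.** A 3-layer fully connected head (32 -> 16 -> 8 -> 1) on Z
with a sigmoid output p = P(PwAD), trained with binary cross-entropy
(negative log-likelihood)

    L_cls = - sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ],

probabilities clamped at 1e-7. The total objective is the unweighted sum
L = L_cls + L_inner + L_outer (per-term weights configurable); inside the
training loop each term is averaged per subject in the batch, which changes
the scale but not the optimum.

**Optimization.** Adam (lr 1e-3, default), batches of 8 subjects, 200
epochs by default. Training is plain-numpy via the in-package reverse-mode
autodiff engine (`gazenest.autodiff`); parameters and activations are
float32 (single precision is ample at these magnitudes — the engine itself
defaults to float64, which the gradient-check and oracle tests use).
Identical data + config + seed gives bitwise-identical parameters.

**Ablation switches.** `use_inner_decoder` / `use_outer_decoder` remove the
respective reconstruction term (exactly zero and outside the gradient);
`use_fusion_layer=False` replaces the adaptive fusion by a plain view mean;
`inner_mode="difference_map"` feeds the flattened x_2 - x_1 (768-dim) per
image instead of the inner latent; `outer_mode="shallow_cnn"` replaces the
outer autoencoder + fusion by a small convolutional net (2 stride-2 convs +
dense) over the stacked view latents. The shallow CNN is deliberately of
the same scale as the rest of the model rather than a deep pretrained-style
topology — the comparison of interest is autoencoder-vs-feedforward
fusion, not capacity.

## Baselines

Per subject the 24 heatmaps (image 1..12 x viewing 1, 2 — fixed order) are
reduced and concatenated, preserving view identity:

* **PCA / KAR** — per-heatmap principal-component (Karhunen-Loeve)
  projection with m components, fit on training-fold heatmaps only; the two
  names are kept distinct to mirror the conventional descriptor pairing.
  The sweep m in {20, 40, 60, 80, 100} is supported.
* **FOU** — magnitudes of the k lowest-spatial-frequency 2-D DFT
  coefficients in a fixed frequency-ordered (zigzag) sequence;
  translation-invariant by construction.

Classifiers: Gaussian Naive Bayes, RBF-SVM (C = 1, gamma = 'scale') and KNN
(k = 5, Euclidean) — scikit-learn implementations, hyperparameters our
choice since none are canonical for this task. Whether the per-heatmap or
per-subject level is the right unit for the descriptor experiment is an
open design point; concatenation at the subject level matches the
multi-view framing used by the main model.

## Evaluation

PwAD is the positive class. Accuracy, precision = TP/(TP+FP), recall =
TP/(TP+FN) and F1 = 2PR/(P+R) are computed from confusion counts; a metric
with a zero denominator is reported as NaN with an explicit flag, never
silently zeroed. ROC curves come from a descending threshold sweep over
unique scores (ties enter together), AUC by trapezoid — equal to the
normalized Mann-Whitney U statistic. Cross-validation is subject-level
stratified four-fold (stratification avoids single-class folds at small n),
each fold trained from scratch; reports aggregate mean +/- sample standard
deviation (ddof = 1) across folds, rounded half-even to two decimals. The
ablation harness runs eight configurations — the progressive module
build-up (encoders only, +inner decoder, +outer decoder, full) and the
component-replacement grid (difference map / inner AE x shallow CNN / outer
AE) — under identical folds.

## Synthetic cohorts

The clinical cohort behind the method is not deposited, so the simulator
reproduces the study conditions and the *qualitative* group contrast; no
quantitative dwell-time statistics are reported anywhere, so absolute
synthetic effect sizes are uncalibrated by construction.

Scenes: 4-8 non-overlapping circular objects (radius 40-80 px) placed
uniformly with margins; one object is marked changed and its bounding
square is the RoI. Gaze: i.i.d. draws from a spatial mixture — an isotropic
Gaussian at screen center (sigma 150 px), equal-weight Gaussians at object
centers (sigma 60 px), and on the second viewing a Gaussian at the RoI
center. Off-screen draws are rejected and redrawn (clipping would pile mass
on the borders and corrupt the central-bias signal). Group profiles on the
second viewing default to (center, objects, RoI) weights (0.70, 0.25, 0.05)
for PwAD and (0.25, 0.45, 0.30) for HC — a large but not trivial margin;
the first viewing renormalizes without the RoI term. Per-subject
heterogeneity is Dirichlet jitter on the weights (concentration 50:
visible variability without class overlap at full effect). The effect size
delta interpolates both groups linearly between their common midpoint
(delta = 0, no signal) and the defaults (delta = 1).

What the simulator does *not* model: saccade sequencing and any temporal
dynamics, blinks/track loss, pupil data, stereoscopic disparity, and
image-content-driven salience. Since every downstream stage consumes only
spatial density, passing tests demonstrate that the pipeline recovers a
spatial group contrast of this kind — not that it would reach any
particular accuracy on clinical recordings.

## Problem sizes and numerical choices

Cohort-level checks run at 30 subjects per group (delta = 1 for
separability, delta = 0 for the null), four-fold CV, 40 training epochs —
a few hundred optimizer steps, needed because the reconstruction terms
dominate the gradient early and the classifier threshold calibrates last.
At this scale the full model separates the simulated groups essentially
perfectly and stays at chance on null cohorts; the ablation ordering
(full >= encoders-only) is assessed as the median over five seeds.
Tolerances: brute-force oracle agreement at 1e-10 (convolution, losses),
1e-12 (AUC identity, metric formulas); smoothing mass conservation at 1e-9.
Degenerate inputs (empty maps, one-class folds, missing views) raise typed
errors rather than producing silent zeros.

## Known limitations

* The synthetic contrast is much cleaner than clinical data; reported
  synthetic accuracies say nothing about clinical performance.
* The i.i.d. gaze model cannot exercise fixation-identification quality;
  the I-DT mode is provided but its defaults are conventions.
* The inner autoencoder is one fixed shallow topology; no architecture
  search was performed.
* Checkpoints store raw parameter arrays + config; no versioning scheme
  beyond the config hash.
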