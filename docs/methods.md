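# Methods

This note documents the models, algorithms and design choices implemented
in `sonomil`, the assumptions behind them, and what the synthetic
validation study does and does not demonstrate.

## The multiple-instance model

A patient is a bag X = {x₁, …, x_N} of N grayscale frames with a single
binary label Y; under the standard MIL assumption Y = max over the (never
observed) instance labels.  N varies freely between bags, so the
architecture must be a set function: every component after the encoder is
symmetric in instance order, and the bag probability is permutation
invariant by construction (verified by test).

**Instance encoder.**  Each frame is mapped to a 512-d feature by a CNN and
the deepest feature map is spatially pooled, so the output is N×512 at any
input resolution whose side is divisible by 8.  The default `tinycnn`
encoder is a stride-2 3×3 stem (8 channels) followed by two 3×3 conv +
2×2 max-pool blocks (16, 32 channels) and a 1×1 projection to 512
channels.  It is deliberately small: the synthetic task is desk-scale and
the whole pipeline must train on one CPU in minutes.  The `vgg13` option
denotes an ImageNet-pretrained backbone fine-tuned end-to-end; it requires
pretrained weights and a deep-learning runtime, and the package reports it
as an unavailable capability rather than silently substituting.

**Attention aggregation (AB-MIL).**  Scores sᵢ = W₂ᵀ tanh(W₁ᵀhᵢ + b₁) + b₂
with W₁ ∈ ℝ^{512×128}, W₂ ∈ ℝ^{128×1}; weights aᵢ = softmax(s)ᵢ over the
bag; bag feature M = Σ aᵢhᵢ.  Two notational points are resolved
explicitly: b₂ is a *scalar* (a per-instance score offset; any constant
cancels inside the softmax, so it is retained only for fidelity to the
published parameterization), and tanh is applied after adding b₁.  The
softmax subtracts the maximum score before exponentiation; the result is
exact because softmax is shift invariant.  Max pooling (elementwise max
over instances) and mean pooling are the ablation baselines.  With W₂ = 0
attention reduces to mean pooling exactly — a limit the tests pin down.

**Head.**  One linear layer on M plus a sigmoid.  The decision threshold
defaults to 0.5 (balanced classes by construction in the simulator); it is
exposed everywhere.  Ties at the threshold count as positive, which makes
the constant-probability-0.5 classifier reproducible: recall 1, accuracy
equal to the positive prevalence.

## Numerical stack

No deep-learning runtime is used: the package carries a small reverse-mode
autodiff engine over NumPy arrays (`sonomil.autodiff`) with convolution as
an im2col matrix product and exact analytic backward passes (the BCE
gradient is implemented directly as sigmoid(z) − y rather than through a
ReLU decomposition, which has the wrong subgradient at z = 0).  Gradients
are verified against central finite differences at 1e−6–1e−4 relative
tolerance, and the attention forward pass against an independent scalar
loop at 1e−6.  Model parameters are float32; evaluation statistics are
float64.  Max-pool backward splits gradients evenly across tied maxima
(ties arise essentially only at ReLU zeros).

## Training

Adam, batch size fixed at one bag (variable N precludes naive batching),
binary cross-entropy, constant learning rate, fixed epoch budget, full
seeding of initialization and bag order.  The reference recipe for a
pretrained backbone is lr 5e−5 for 100 epochs, and those are
`TrainConfig`'s defaults; the synthetic studies train the `tinycnn`
encoder *from scratch*, for which 5e−5 is far too conservative, so every
study configuration in this package uses the conventional Adam rate 1e−3
and 10–20 epochs.  A validation split (15% of training bags, stratified)
selects the best checkpoint by validation AUC; the test partition is never
touched during training.  Splits are always at the patient level
(train/test patient sets verified disjoint across seeds), mirroring the
3:1 examination-level protocol such models are trained under clinically.
Augmentation (horizontal flip p = 0.5, contrast jitter ±20%, rotation
±15°, scale 0.9–1.1, translation ≤10% — conventional mild ranges, drawn
independently per image) is available but off in the synthetic studies:
the simulator already randomizes pose and the studies aim at minimal,
reproducible conditions.

## The simulator

`sonomil.simulate` generates the study conditions: bags of 4–12 speckled
64 px frames (the per-examination frame count distribution of real
datasets is rarely published; 4–12 brackets a typical mean of ~8),
balanced classes, background intensity 0.6, additive Gaussian speckle
(σ = 0.08) clipped to [0,1].  Negative instances carry a regular,
homogeneous ellipse at a fixed mild contrast (0.1) — the benign
phenotype; positive instances carry an irregular ellipse (low-order
angular perturbation of the margin) darker than background by
`lesion_contrast`, stippled with 3–8 bright 1–2 px spots emulating
microcalcifications.  A positive bag of size N contains exactly
max(1, round(witness_rate·N)) positive instances; a negative bag contains
none.  One seed sequence per dataset spawns one child per bag, so datasets
are bit-reproducible and any bag can be regenerated alone.  Ground-truth
instance labels and lesion/spot masks are recorded for evaluation only.

What the simulator does **not** emulate: physical speckle statistics,
acoustic shadowing, probe/depth variation, operator framing, inter-patient
anatomy, or label noise.  Passing the synthetic studies therefore shows
that the implementation is correct and that the architecture can learn
bag-level discrimination, key-instance selection and spatial localization
from weak labels — not that it reaches any particular clinical accuracy.

## Evaluation statistics

Accuracy, precision, recall and F1 from the confusion matrix at the chosen
threshold; AUC by the rank (Mann–Whitney) formulation with ties counted ½,
identical to the trapezoidal area under the ROC curve (asserted exactly
against an O(n²) pair-count oracle).  95% CIs use a stratified
patient-level percentile bootstrap, 1000 resamples, seeded: resampling
patients (not frames) respects the clustering of frames within patients,
and stratification keeps every resample two-class so AUC stays defined.
Two models are compared by a two-sided paired t-test and Cohen's d for
paired data (mean difference / SD of differences, bands at the
conventional 0.2 / 0.5 / 0.8 cutoffs) on per-resample metric values over a
*shared* resample index set — evaluating both models on identical patient
resamples is what makes the samples paired.  Zero-variance differences are
reported as a degenerate comparison (d = 0, p undefined) rather than an
error.  The ablation harness trains one arm per pooling operator with
everything else identical and audits that arm configurations differ only
in the pooling field.

## Interpretability

Attention reports rank instances by weight (deterministic index
tie-break).  Grad-CAM targets the deepest convolutional layer of the
active encoder: channel weights are the spatial mean of ∂(bag
logit)/∂(activation), the map is ReLU of the weighted activation sum,
max-normalized per instance and bilinearly upsampled to frame size; an
all-gated map is returned flat with a flag rather than raised.  One
design decision was revised by measurement here: with *average* spatial
pooling feeding the head, the shallow encoder tends to encode the dark
lesion as suppression of background-texture channels, which inverts the
saliency map (heat on background); with *max* spatial pooling the gradient
flows to the activating location and saliency anchors to the lesion
(localization 0.92/1.00 vs 0.81/0.64 across two seeds at identical AUC).
Spatial max pooling is therefore the encoder default; average remains
available.

## Validation study sizes

Chosen to exercise the full pipeline at CPU scale: the main study uses 250
bags per seed (170 train / 30 validation / 50 test), 64 px frames, witness
rate 0.5, lesion contrast 0.5, 20 epochs, three seeds; the pooling
ablation uses 150 bags per seed (102/18/30), witness rate 0.25, contrast
0.3, bags of 6–12 frames, 12 epochs, five seeds — a regime where mean
pooling's dilution of the minority witnesses is measurable.  The
bootstrap-calibration check simulates a Bernoulli(0.8)-accurate classifier
over 500 patients and verifies ≥90% CI coverage across 100 replicates.

## Known limitations

- The NumPy stack is single-threaded-ish and desk-scale; it is not a
  platform for 512 px clinical volumes, though the architecture accepts
  any resolution divisible by 8.
- `vgg13` transfer learning is an interface, not an implementation, until
  pretrained weights are available in the environment.
- Grad-CAM at the deepest layer has 8×8 spatial resolution at 64 px input;
  fine structure below that scale is only visible through upsampling.
- The paired-comparison unit (shared bootstrap resamples) is one defensible
  choice among several; per-run pairing across repeated trainings is the
  main alternative and would measure run-to-run variance instead of
  patient-sampling variance.
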