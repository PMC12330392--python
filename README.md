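# sonomil

Attention-based multiple-instance learning (MIL) for patient-level risk
classification from variable-length sets of ultrasound-like images.

## The problem

An ultrasound examination produces a variable number of frames per patient,
but clinical ground truth (e.g. a C-TIRADS-style low-risk / high-risk call)
exists only at the patient level: no one labels individual frames, and a
single frame of a high-risk patient may look perfectly benign.  This is the
classic *multiple-instance* setting — each patient is a **bag** of unlabeled
**instances** (frames), and a bag is positive iff at least one instance is.
`sonomil` is for researchers who want to train, evaluate and interrogate
bag-level classifiers in this setting without access to clinical data: it
ships a synthetic bag simulator with controllable difficulty, the MIL
network, the bag-level training loop, the bootstrap evaluation statistics,
and the interpretability tools, all runnable on one CPU.

## The model

Each frame is encoded by a CNN into a 512-dimensional feature, giving an
instance feature matrix **H** = (h₁, …, h_N) ∈ ℝ^{N×512}.  The bag feature is
a learned convex combination of the instance features (AB-MIL attention):

    sᵢ = W₂ᵀ tanh(W₁ᵀ hᵢ + b₁) + b₂        W₁ ∈ ℝ^{512×128}, W₂ ∈ ℝ^{128×1}
    aᵢ = exp(sᵢ) / Σⱼ exp(sⱼ)
    M  = Σᵢ aᵢ hᵢ

and the bag probability is `sigmoid(wᵀM + b)`.  Element-wise **max** and
**mean** pooling are available as ablation baselines.  Training is Adam with
a batch of one patient per step and binary cross-entropy on the bag
probability.  Interpretability comes in two deliberately separate forms:
the attention weights aᵢ rank *which frames* drove the decision, and
Grad-CAM on the deepest convolutional layer shows *where in a frame* the
evidence sits.

The working encoder (`tinycnn`) is a compact from-scratch CNN so everything
runs offline on CPU; the interface also names an ImageNet-pretrained
`vgg13` backbone, which raises a clear capability error when its weights
are unavailable.

## Worked example

`examples/02_train_attention_mil.py` trains on 80 synthetic bags (weak
labels only) and evaluates on held-out patients:

```
epoch  1  train BCE 0.2150  val AUC 1.000
epoch  2  train BCE 0.0038  val AUC 1.000
...
held-out test AUC on 20 unseen patients: 1.000
```

The falling BCE shows the bag-level objective being learned; the held-out
AUC of 1.000 says the model ranks every unseen high-risk patient above
every low-risk one in this easy regime (lesion contrast 0.5, witness rate
0.5).  `examples/05_explain_predictions.py` then interrogates a positive
test bag of a trained model:

```
patient P0033: risk probability 0.997
rank  frame  attention  truly-positive?
   1     1    0.254      True
   2     2    0.225      True
   3     0    0.203      True
   4     4    0.203      True
   5     6    0.025      False
...
Grad-CAM on the top frame: mean heat inside lesion 0.657 vs outside 0.041
```

The four frames that truly contain the lesion receive essentially all the
attention mass, and the saliency map concentrates inside the simulator's
lesion mask.  The other examples cover the simulator (`01`), bootstrap
confidence intervals and paired model comparison (`03`), and the
max/mean/attention pooling ablation (`04`).

A command-line interface wraps the same pipeline
(`sonomil simulate|train|predict|eval|explain|ablate`, YAML-configured,
every run writing a resolved config and a JSONL log for provenance).

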