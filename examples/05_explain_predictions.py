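"""Interpretability: which frames mattered (attention) and where (Grad-CAM).

After training, the attention weights rank a patient's frames by their
contribution to the bag decision, and Grad-CAM maps the bag logit's
gradient onto each frame's deepest convolutional activations to show the
image region the model used.  On synthetic data both can be scored against
the simulator's hidden ground truth.
"""

import numpy as np

import sonomil as sm
from sonomil.study import run_synthetic_study

# small-but-real training run (~1 min on one CPU)
study = run_synthetic_study(seed=1, n_bags=120, epochs=10)
model = study.model
print(f"held-out test AUC: {study.test_auc:.3f}")

bag = next(b for b in study.test_bags if b.bag_label == 1)
prediction = model.predict(bag)
report = sm.attention_report(prediction, top_k=3)
print(f"\npatient {bag.patient_id}: risk probability {prediction.probability:.3f}")
print("rank  frame  attention  truly-positive?")
for entry in report.entries:
    truth = bag.instance_labels[entry["index"]]
    print(f"  {entry['rank']:2d}   {entry['index']:3d}    {entry['weight']:.3f}      {bool(truth)}")

top = report.key_instances[0]
heatmap = sm.grad_cam(model, bag, top)
mask = bag.masks[top]["lesion"] | bag.masks[top]["spots"]
print(f"\nGrad-CAM on the top frame: mean heat inside lesion "
      f"{heatmap.values[mask].mean():.3f} vs outside {heatmap.values[~mask].mean():.3f}")
out = sm.render_overlay(np.asarray(bag.images[top]), heatmap,
                        f"scratch/{bag.patient_id}_{top:03d}_cam.png")
print(f"overlay written to {out}")
print("-> higher heat inside the mask means the saliency found the lesion")
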