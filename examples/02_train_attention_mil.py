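"""Train the attention-MIL classifier on synthetic bags and watch it learn.

The model sees only bag-level labels (one per patient); instance labels
exist in the simulator but are never shown to training.  Training follows
the bag-level recipe: Adam, one patient per optimization step, binary
cross-entropy on the bag probability.  The printed validation AUC shows the
model learning to rank positive examinations above negative ones.
"""

import sonomil as sm

bags = sm.generate_dataset(sm.SimConfig(n_bags=80, image_size=64, seed=1))
spec = sm.PreprocessSpec(target_size=64)
bags = [sm.preprocess(b, spec) for b in bags]

trainval, test = sm.split_by_patient(bags, train_frac=0.75, stratify=True, seed=1)
train_bags, val_bags = sm.split_by_patient(trainval, train_frac=0.85,
                                           stratify=True, seed=1)

model = sm.MILModel(pooling="attention", seed=1)
result = sm.train(train_bags, val_bags, model,
                  sm.TrainConfig(lr=1e-3, epochs=8, seed=1))

for record in result.history:
    print(f"epoch {record['epoch']:2d}  train BCE {record['train_loss']:.4f}  "
          f"val AUC {record['val_auc']:.3f}")
print(f"best epoch by validation AUC: {result.best_epoch}")

preds = sm.predict_bags(model, test)
auc = sm.auc_score(preds['label'].to_numpy(), preds['probability'].to_numpy())
print(f"held-out test AUC on {len(test)} unseen patients: {auc:.3f}")
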