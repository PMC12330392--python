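"""Generate a synthetic bag dataset and write it to disk.

Each bag stands for one patient's ultrasound examination: a variable number
of grayscale frames sharing one weak binary label.  A bag is positive iff
at least one frame shows the high-risk lesion phenotype (irregular margin +
bright punctate spots); the witness rate controls how many frames do.
"""

import numpy as np

import sonomil as sm

config = sm.SimConfig(n_bags=20, bag_size_range=(4, 12), witness_rate=0.5,
                      lesion_contrast=0.5, image_size=64, seed=7)
bags = sm.generate_dataset(config)

n_pos = sum(b.bag_label for b in bags)
sizes = [len(b) for b in bags]
print(f"bags: {len(bags)} ({n_pos} positive), "
      f"frames per bag: min {min(sizes)} / mean {np.mean(sizes):.1f} / max {max(sizes)}")
for bag in bags[:3]:
    print(f"  {bag.patient_id}: label={bag.bag_label}, "
          f"{len(bag)} frames, witnesses={sum(bag.instance_labels)}")

manifest = sm.write_manifest(bags, "scratch/example_dataset")
print(f"wrote 8-bit PNGs + manifest to {manifest}")
print("(one manifest row per frame; all frames of a patient share its label)")
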