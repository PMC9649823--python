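"""Train the tiny segmentation preset on phantoms and measure kidney volumes.

A shortened demonstration of the full training path (the test suite runs
the 30-epoch version): the tiny UNETR-style network (64^3 patch, 4
transformer blocks) is trained on 8 noiseless phantoms with 2 held out,
then the held-out scans are segmented by sliding-window inference,
post-processed to the two bilateral kidney components, and measured by the
voxel-count method. Takes a few minutes on one CPU.
"""
import numpy as np

from renovol.imaging import ClassScheme, LabelMap
from renovol.nn import (
    NetworkConfig,
    TrainConfig,
    map_labels_to_network_classes,
    restore_network,
    train,
)
from renovol.nn.infer import sliding_window_probabilities
from renovol.phantom import generate_phantom, phantom_suite
from renovol.postvolume import postprocess_labels, voxel_count_volume
from renovol.preprocess import TARGET_SPACING, normalize_intensity

cases, gts = [], []
for spec in phantom_suite(10, base_seed=300, noise_sigma=0.0):
    vol, gt = generate_phantom(spec)
    cases.append((normalize_intensity(vol).voxels,
                  map_labels_to_network_classes(gt.labels.labels, gt.labels.scheme)))
    gts.append(gt)

ckpt = train(
    cases[:8], cases[8:], NetworkConfig.tiny(0), TrainConfig.tiny(0, epochs=25),
    log=lambda e, l, d: print(f"epoch {e:2d}: loss {l:.4f}"
                              + (f"  val DSC {d:.4f}" if d is not None else "")),
)
print(f"best checkpoint: epoch {ckpt.epoch}, validation parenchyma DSC {ckpt.val_dsc:.4f}")

net = restore_network(ckpt)
for (image, _), gt in zip(cases[8:], gts[8:]):
    probs = sliding_window_probabilities(net, image)
    pred = np.argmax(probs, axis=0).astype(np.uint8)
    labels = postprocess_labels(LabelMap(pred, TARGET_SPACING, ClassScheme.model_output()))
    auto = voxel_count_volume(labels).volumes_cm3["parenchyma"]
    true = gt.analytic_volumes_cm3["parenchyma"]
    print(f"parenchyma volume: automated {auto:6.2f} cm3, analytic truth {true:6.2f} cm3"
          f"  (relative error {abs(auto - true) / true:.3f})")
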