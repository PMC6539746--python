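"""Visualize convolution feature maps with and without thresholding.

Trains a small network briefly on phantoms, then writes per-feature-map
maximum-intensity projections of the first convolution layer for the same
subdural scan, once raw and once thresholded. With thresholding the lesion's
edges stand out because the shared tissue range has been zeroed.
"""

import numpy as np

from hemoct.experiments import visualize_features
from hemoct.model import table2_spec
from hemoct.phantom import PhantomConfig, generate_arrays
from hemoct.thresholding import fit_threshold_from_volumes
from hemoct.training import TrainConfig, train
from hemoct.volumes import ClassLabel

vols = generate_arrays({ClassLabel.N: 80, ClassLabel.ASDH: 80}, PhantomConfig(seed=5))
spec = table2_spec(2, filters=(8, 16, 32), dense_units=64)
X = np.stack([v.intensities for v in vols])
y = np.array([int(v.label == ClassLabel.ASDH) for v in vols])
net, _ = train(spec, X, y, TrainConfig(epochs=2, seed=5))

model = fit_threshold_from_volumes(
    [v for v in vols if v.label == ClassLabel.N],
    [v for v in vols if v.label == ClassLabel.ASDH],
)
scan = next(v for v in vols if v.label == ClassLabel.ASDH)
raw = visualize_features(net, scan, 0, "scratch/panels/raw")
thr = visualize_features(net, scan, 0, "scratch/panels/thresholded", threshold_model=model)
print(f"wrote {len(raw)} raw and {len(thr)} thresholded panels under scratch/panels/")
print(f"(threshold cutoff {model.cutoff:.1f} HU)")
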