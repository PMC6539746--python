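"""Fit the class-pair intensity threshold on phantoms and apply it.

Averages per-class intensity histograms of normal vs subdural phantoms,
searches for the cutoff that keeps >= 95% of the abnormal class's excess
intensity mass, and shows its effect on one scan.
"""

import numpy as np

from hemoct.phantom import PhantomConfig, generate_arrays
from hemoct.thresholding import apply_threshold, fit_threshold_from_volumes
from hemoct.volumes import ClassLabel

# class-average histograms need a decent fitting set: with too few noisy
# scans, sampling noise in the air band eats the retention budget
vols = generate_arrays(
    {ClassLabel.N: 80, ClassLabel.ASDH: 80}, PhantomConfig(seed=11)
)
normals = [v for v in vols if v.label == ClassLabel.N]
subdurals = [v for v in vols if v.label == ClassLabel.ASDH]

model = fit_threshold_from_volumes(normals, subdurals)
print(f"fitted cutoff: {model.cutoff:.1f} HU")
print(f"retained excess-mass fraction: {model.retained_difference_fraction:.4f}")
# The cutoff lands between brain tissue (~30 HU) and acute blood (~70 HU):
# everything the two classes share is discarded, the blood band survives.

v = subdurals[0]
out = apply_threshold(v, model)
kept = np.mean(out.intensities > 0)
print(f"voxels kept after thresholding: {kept:.1%} (blood and bone only)")
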