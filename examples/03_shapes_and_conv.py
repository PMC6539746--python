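"""Architecture shape arithmetic and the 3D convolution primitive.

Prints every layer's output size for the default network on a 50x50x28 scan
(note the ceiling-mode pooling chain 50->25->13->7 and the 25,088-wide
flatten) and demonstrates the convolution against an identity kernel.
"""

import numpy as np

from hemoct.model import conv3d_forward, count_parameters, layer_output_shapes, table2_spec

spec = table2_spec(n_classes=2)
shaped_layers = [l for l in spec.layers if type(l).__name__ != "Dropout"]
for layer, shape in zip(shaped_layers, layer_output_shapes(spec, (50, 50, 28))):
    print(f"{type(layer).__name__:10s} -> {shape}")
print(f"total parameters: {count_parameters(spec, (50, 50, 28)):,}")

# a centered delta kernel reproduces its input exactly
x = np.random.default_rng(0).normal(size=(5, 5, 4, 1))
k = np.zeros((3, 3, 3, 1, 1))
k[1, 1, 1, 0, 0] = 1.0
out = conv3d_forward(x, k, np.zeros(1), activation="none")
print("identity-kernel max deviation:", np.abs(out - x).max())
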