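"""Inspect the encoder architectures and their dimension arithmetic.

Every module encodes its input to 20 dimensions; the fusion head therefore
has width 20 x (number of enabled modules).  The raw encoder's kernel-1
convolution reduces the pre-flatten width from 1920 to 40, shrinking the
final fully-connected layer from 38,400 to 800 weights (plus 192 for the
reduction itself).
"""

import numpy as np

from ecgfusion.model import (
    FusionModel,
    ModuleConfig,
    all_module_combinations,
    build_qrs_single_encoder,
    build_raw_encoder,
    count_weights,
    shape_trace,
)

rng = np.random.default_rng(0)
print("raw encoder (channels, length) after each layer:")
for shape in shape_trace(build_raw_encoder(rng), (12, 5000)):
    print("  ", shape)
print("hypothetical FC on the 1920-dim flatten:", count_weights((1920, 20)), "weights")
print("actual FC on the 40-dim flatten:        ", count_weights((40, 20)), "weights")
print("kernel-1 reduction conv:                ", count_weights((96, 2, 1)), "weights")

print("\nbeat encoder g: R^(12x100) -> R^24:")
print("  final shape:", shape_trace(build_qrs_single_encoder(rng), (12, 100))[-1])

print("\nfusion widths of all 15 module combinations (2 classes):")
for combo in all_module_combinations():
    model = FusionModel(ModuleConfig(enabled=combo, n_classes=2))
    print(f"  {'+'.join(combo):44s} -> {model.fusion_fc.in_features}")
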