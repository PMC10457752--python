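"""Audit the period-window classifier architecture.

Builds the nine-layer 1-D CNN for input windows of 1495 samples and five
artery classes, and prints each stage's output length and weight count —
the totals are what make the network small enough to train on a few
hundred periods per class.
"""

from pulsesite import ARTERY_CLASSES
from pulsesite.model import build_model, count_parameters

model = build_model(input_len=1495, n_classes=5, classes=list(ARTERY_CLASSES))

print(f"{'Layer Type':<18}{'Channels':>9}{'Length':>8}{'Params':>8}")
for row in model.audit:
    ch = "-" if row.n_channels is None else row.n_channels
    par = row.n_params if row.n_params else "-"
    print(f"{row.layer_type:<18}{ch:>9}{row.length_dim:>8}{par:>8}")

counts = count_parameters(model)
print(f"\ntotal trainable parameters : {counts['total_trainable']}")
print(f"non-trainable parameters   : {counts['total_nontrainable']}")
print("\nOnly the two convolutions and two dense layers carry weights"
      f" ({counts['per_layer']}); pooling, flatten and dropout are free.")
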