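"""Generate the synthetic multi-artery dataset and characterize each site.

Builds 3 recordings for each of the five acquisition sites (brachial A,
carotid B, radial C, posterior tibial D, ulnar E), then decomposes each
channel into baseline + pulsatile component and prints the per-site mean
pulse amplitudes with their sensitivity (pulse amplitude as a percentage
of the maximum measured impedance).
"""

import pulsesite as ps
from pulsesite import preprocess

recordings = ps.make_dataset(None, n_recordings_per_class=3, seed=1,
                             duration=30.0)
print(f"{len(recordings)} recordings, "
      f"{recordings[0].n_samples} samples each at {recordings[0].fs:g} Hz\n")

table = preprocess.sensitivity_table(recordings)
ebi = table[table.channel == "z_100k"]
print("EBI at 100 kHz (ohm):")
print(ebi[["site", "delta_mean", "delta_sd", "sensitivity_pct"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
rppg = table[table.channel == "rppg"]
print("\nrPPG (V):")
print(rppg[["site", "delta_mean", "delta_sd"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))

print("\ndelta_mean is the mean per-beat peak-to-trough amplitude of the"
      "\npulsatile component; sensitivity_pct = 100 * delta_mean / max(Z)."
      "\nThe carotid site (B) shows by far the largest impedance pulse and"
      "\nthe highest sensitivity; the posterior tibial site (D) leads on"
      "\nthe optical channel.")
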