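"""Fuse, binarize and extract the 5x5 fall template from one recording.

The 5xN bipolar matrix is scanned by a sliding 5x5 window; the window with
the most +1 entries becomes the stored pattern (one entry per neuron).
"""

import hopfall as hf

rec = hf.generate_activity("Fall", seed=1)
bm = hf.binarize(hf.fuse_axes(rec))
tpl = hf.extract_template(bm, class_label="Fall")

print(f"binary matrix shape: {bm.entries.shape}")
print(f"chosen window start: column {tpl.window_start}")
print("template grid (+1 = feature above threshold):")
for row in tpl.grid:
    print("  " + " ".join(f"{v:+d}" for v in row))
print("\nA saturated (+1) template means all five fused features stayed above")
print("their thresholds for the whole 5-sample window of the fall transient.")
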