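"""Hebbian one-shot training and associative recall of a corrupted probe.

Stores the fall template in a 25-neuron Hopfield network and shows that a
probe with 8 of 25 bits flipped relaxes back to the stored pattern, with
the network energy decreasing monotonically along the way.
"""

import numpy as np

import hopfall as hf

rec = hf.generate_activity("Fall", seed=1)
tpl = hf.extract_template(hf.binarize(hf.fuse_axes(rec)), class_label="Fall")
W = hf.train_hebb(tpl, eta=1.0)

rng = np.random.default_rng(0)
probe = tpl.vector.astype(float)
probe[rng.choice(25, size=8, replace=False)] *= -1

res = hf.recall(W, probe, mode="async", seed=7)
print(f"corrupted bits: 8/25, initial energy {res.energy[0]:.1f}")
print(f"converged: {res.converged} after {res.sweeps} sweep(s), "
      f"final energy {res.energy[-1]:.1f}")
print(f"recalled == stored template: {np.array_equal(res.v, tpl.vector.astype(float))}")
print(f"energy non-increasing: {bool((np.diff(res.energy) <= 0).all())}")
print("\nThe stored pattern sits at the energy minimum (-300 for a single")
print("25-bit pattern); corrupted probes roll downhill into that attractor.")
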