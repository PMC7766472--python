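"""Recall through the behavioral op-amp circuit, with and without noise.

Weights become normalized conductances (sign = inverting vs non-inverting
input), each neuron is an RC-relaxing summing amplifier with a tanh
transfer, and the thresholded steady state is compared with the ideal
digital recall.
"""

import numpy as np

import hopfall as hf

rec = hf.generate_activity("Fall", seed=1)
tpl = hf.extract_template(hf.binarize(hf.fuse_axes(rec)), class_label="Fall")
W = hf.train_hebb(tpl)
params = hf.map_weights_to_circuit(W)
target = tpl.vector.astype(float)

probe = target.copy()
probe[:6] *= -1  # corrupt six neurons

for noise in (0.0, 0.05, 0.1):
    config = hf.CircuitConfig(gain=10.0, noise_sd=noise, duration=10.0)
    out = hf.simulate_circuit(params, config, probe, seed=3)
    ok = np.array_equal(out.readout, target)
    print(f"noise_sd={noise:.2f}: steps={out.steps:4d} "
          f"recalled template exactly: {ok}")
print("\nAt gain 10 the analog steady states coincide with the digital fixed")
print("points; moderate summing-node noise does not break the recall because")
print("the attractor's basin absorbs it.")
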