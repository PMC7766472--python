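# Methods

## Problem and model

The package detects human falls in 9-axis IMU traces by template matching
with a discrete Hopfield network used as an associative memory. The
appeal of the approach is one-shot learning (a single fall sample defines
the stored pattern) and a direct hardware realization (each neuron is a
summing op-amp whose resistor ratios encode the weights), which this
package models behaviorally in software.

The processing chain is: 9 channels → five fused features M1..M5 →
strict thresholding into a 5×N bipolar matrix → best 5×5 window as the
pattern template → Hebbian weights → associative recall of test
templates → cosine decision against the fall template.

## Discrete network

- **Bipolar convention.** Neuron outputs are ±1 throughout. The
  {0, 1} rendering of the threshold function is equivalent under the
  affine map v ↦ 2v − 1; bipolar states are what make the signed Hebbian
  weights (±η per pattern term) meaningful.
- **Tie rule.** A zero local field keeps the previous state (default).
  Forcing the low state instead (`tie="down"`) is supported; with
  all-zero weights it collapses every state to −1, whereas keeping the
  state makes the identity the fixed-point map, which avoids spurious
  flips in the heavily-corrupted regime (at exactly 12/25 corrupted bits
  the clean neurons of a single stored pattern have zero field).
- **Energy.** E(v) = −½ Σ Wᵢⱼ vᵢ vⱼ − Σ Iᵢ vᵢ, the standard quadratic
  Lyapunov function; with symmetric zero-diagonal W it is non-increasing
  under single-neuron updates, which the tests assert over 1000 random
  trajectories.
- **Learning rate.** η = 1 by default; any η > 0 rescales fields without
  changing their signs, so recall is η-invariant (asserted).
- **Update order.** Asynchronous mode draws a fresh seeded permutation
  each sweep; convergence means one full sweep with no change.
- **External inputs.** The bias inputs Iᵢ default to zero; no value is
  prescribed by the method, and the fall memory needs none.
- **Capacity note.** The network stores one template per run of the
  pipeline. Multi-pattern storage is implemented and tested (the N=4
  two-pattern example, brute-force fixed-point checks) but Hebbian
  capacity (~0.14 N) is not the object of study here.

## Analog circuit model

The hardware neuron is a summing amplifier: synaptic resistors feed the
inverting or non-inverting input depending on the weight sign, a constant
bias source adds the external input, and the KCL current balance at the
summing node with the node capacitance gives the textbook RC relaxation

    τ du/dt = −u + G v + bias + noise(t),   v = rails · tanh(gain · u).

Design choices, all free parameters of `CircuitConfig` because no
component values are prescribed:

- **Conductance normalization.** G = W / max|W| (max |G| = 1); zero
  weights are open circuits. Scaling W by a positive constant does not
  change the sign structure, so the high-gain fixed points are unchanged.
- **Integration.** Explicit Euler, dt = τ/100 by default, duration 40 τ
  with early stop once |du|∞ < 1e−12 (noise-free runs only). Euler is
  adequate because the dynamics are a contraction toward the attractor at
  these settings; the numerically-checked Lyapunov descent (tolerance
  1e−6·|E|) guards the step size. Any |u| above 1e6 × rails raises an
  explicit divergence error.
- **Gain.** Default 10. In the high-gain limit the amplifier approaches
  the sign function and the thresholded steady states coincide with the
  digital fixed points; the agreement experiment (200 random initial
  states) measures this at ≥ 95% and in practice reaches 100%.
- **Noise.** White Gaussian at the summing node, seeded, sd in volts
  (rails = 1 by default, so 0.05–0.1 means 5–10% of the rails). The
  stored template's fields are ±24 conductance units deep, so recall
  tolerates this noise comfortably; the tests only assert monotone
  non-increasing success versus noise.
- **Readout.** Sign of the final output voltage; an exactly-zero output
  keeps the corresponding initial state, mirroring the digital tie rule.

## Feature extraction

M1..M3 are products of (|axis|+1) over one sensor triple, hence ≥ 1 and
sensitive to overall motion intensity per sensor; M4 and M5 are signed
cross-sensor products that respond to the coordinated gyro/accel/magneto
excursion of a fall. They are implemented exactly as specified, without a
posture-estimation interpretation. Thresholds t = [16, 24, 32, 40, 48]
operate directly on the fused values and are fixed constants of the
method (originally tuned by trial and error, not learned here).

Two readings of the thresholding step exist and both are implemented:
row i thresholds feature M(i+1) with t[i] (default, `per-feature` —
chosen because all five formulas are computed, so all five should be
used), or all five rows threshold one feature at five levels
(`thermometer`). The optional `flip` transform mirrors the extracted
window left-right before storage; a pattern and its mirror are equally
valid Hebbian templates, so it is off by default. Window selection
maximizes the +1 count over all contiguous 5-column windows (stride 1,
0-based, earliest-start tie break); the maximal-activation window is the
natural proxy for "the fall event" since no other criterion is
prescribed.

## Synthetic data generator

No real recordings ship with the package, so a seeded generator emulates
the five activity classes at the stated capture conditions (50 Hz, 5–10 s;
6 s default). Signal model per channel: Gaussian baseline noise
(sd 0.05, arbitrary units) plus a deterministic class envelope — half-sine
transient for Fall/SitDown/StandUp (with a seeded onset jitter), a
phase-jittered 2 Hz sinusoid for Walk, flat for "Under" (undefined in the
source material; treated as a low-motion class).

Fall peak amplitudes (Gx=3, Gy=0.3, Gz=3, Ax=12, Ay=10, Az=0.5, Mx=0.3,
My=10, Mz=3) were chosen once so that at the transient maximum all five
fused features clear their thresholds with margin (M1≈20.8 > 16,
M2≈214 > 24, M3≈57 > 32, M4≈172 > 40, M5≈57 > 48) for a contiguous run of
more than 5 samples, while SitDown/StandUp peaks (≈2 on the inertial
channels) cross only the lowest one or two thresholds, Walk stays
sub-threshold, and Under stays near baseline. Units are arbitrary because
the thresholds are taken to act directly on the fused values.

**What passing on this data does and does not show.** The generator
reproduces the qualitative structure the method relies on — a fall is a
brief, large, multi-sensor transient — but not real fall kinematics,
device noise spectra, orientation effects or inter-subject variability.
The end-to-end accuracy on this synthetic set (100% at the default
settings, asserted against a conservative 0.85 bar) therefore validates
the machinery, not the field performance of the method; accuracies
reported on real recordings elsewhere are not reproducible from this
package and are not claimed by it.

## Evaluation

Fall is the positive class. The decision is cosine similarity to the fall
template ≥ 0.8; the threshold is a package default (no value is
prescribed) and any value in (−1, 1] can be configured — on bipolar
25-vectors, 0.8 corresponds to allowing at most 2 mismatched neurons.
Accuracy is (TP+TN)/(TP+FP+TN+FN). The pipeline trains on the first fall
recording and holds it out of the evaluation set.

## Problem sizes

Defaults chosen for desk-scale runs: 10 recordings per class (50 total)
end to end, 200 random initial states for the analog/digital agreement
experiment, 100 seeds per noise level, 1000 asynchronous trajectories for
the energy check, and exhaustive enumeration up to N = 10 for the
brute-force fixed-point oracle. All complete in seconds to a couple of
minutes on one CPU.

## Known limitations

- The synthetic fall template saturates to all +1 at the default
  calibration; richer (non-saturated) templates arise only with narrower
  envelopes or harder thresholds, and the classifier has not been
  exercised on such regimes beyond the property tests.
- The circuit model is behavioral: no op-amp non-idealities (slew,
  offset, finite bandwidth), no absolute component values, no SPICE-level
  validation.
- Fixed thresholds; no adaptation to sensor placement or subject.
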