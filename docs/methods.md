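# Methods

## Model and loss

The classifier is a fully-connected 30-5-2 network. Hidden pre-activations
Z1 = W1ᵀx + b1 pass through Sqish; output pre-activations Z2 = W2ᵀA1 + b2
pass through LogSQNL, whose range [0, 1] makes the two outputs directly
comparable against one-hot targets (benign = [1,0], malignant = [0,1]).
Prediction is the argmax of A2, ties resolved to the lowest index.

The training loss is L = ½ Σⱼ (A2ⱼ − yⱼ)². This choice is forced by the
layer-gradient structure the package implements: every gradient term
carries the bare factor (A2 − y), which is exactly the derivative of this
loss and of no other common one.

Both activations are piecewise quadratics with breakpoints at −2, 0 (and 2
for LogSQNL). At an exact breakpoint the branch listed first in the case
order applies (z = 0 takes the z ≥ 0 branch, z = −2 the −2 ≤ z branch);
function values agree by continuity either way, so the convention only
fixes which one-sided derivative is reported at a breakpoint — a
deterministic tie-break, not a modelling decision. Sqish has a dead region
below −2 (zero value and zero gradient, like a ReLU that has died), a
global minimum of −0.5 at z = −1, and an unbounded positive branch;
LogSQNL saturates at both ends, so output gradients vanish outside
(−2, 2).

## Gradient modes

Backpropagation is implemented twice:

* **`chain_rule`** (default) — the complete analytic gradient:
  δ2 = (A2 − y)·logsqnl′(Z2), δ1 = (W2 δ2)·sqish′(Z1), with
  dW2 = A1 δ2ᵀ, dW1 = x δ1ᵀ and the biases taking the deltas.
* **`paper_literal`** — the published hidden-layer update, which gates
  each (hidden i, output j) term on the joint sign pattern of (Z1ᵢ, Z2ⱼ):
  the term is (2 − Z2)(16 + Z1)/64 when both lie in [0, 2],
  (2 + Z2)(1 + Z1)/4 when both lie in [−2, 0), and zero otherwise — in
  particular for mixed signs, and for Z1 > 2 even though Sqish's positive
  branch extends there. The two modes coincide exactly when every
  (Z1ᵢ, Z2ⱼ) pair falls in one of the two shared regimes (this is tested
  on 1-1-1 networks in both regimes). As printed, the update also carries
  a stray A1 factor that would make it disagree with the chain rule by a
  multiplicative A1 even in the shared regimes; the literal mode keeps the
  printed branch polynomials and joint conditions but drops that factor,
  which is the only internally consistent reading. Mixed-sign
  pre-activations occur constantly in practice, so the default is the
  complete gradient; the literal mode is retained for fidelity studies of
  the restricted update.

Correctness of the analytic gradient is established against a
central-finite-difference oracle (h = 1e-6, tolerance 1e-5) on random
instances whose pre-activations are kept at least 0.05 away from the
breakpoints — finite differences straddling a breakpoint would measure a
mixture of two branches and are not a valid oracle there.

## Optimizer and defaults

Classical momentum: v′ = µv − η·g, θ′ = θ + v′, velocities initialized to
zero. Defaults are the grid-searched operating point of the reference
system: η = 1/3, µ = 0.9, batch size 100, 4300 epochs. Mini-batch
gradients are **averaged**, not summed, so η is scale-free in the batch
size; with summed gradients the same η would correspond to a 100× larger
step. Shuffling and initialization (zero-mean Gaussians scaled by
1/√fan_in, zero biases) both derive from the single config seed, making
runs bit-reproducible. Grid search evaluates the full Cartesian product of
candidate hyperparameters on a stratified held-out slice (default 20 %),
ties broken by grid order.

Test-scale runs in this repository train for 60–200 epochs rather than
4300: the synthetic task converges to its ceiling within ~150 epochs, and
the shorter schedule is the package's chosen problem size for routine
verification. The full schedule remains the config default.

## Fixed-point datapath

All datapath values use Q4.7: 11-bit two's complement, 4 integer bits
(sign included), 7 fractional bits, range [−8, 8 − 2⁻⁷], step 2⁻⁷. The
sign lives inside the integer bits because standardized inputs are
zero-centered and must represent negatives. Quantization rounds to
nearest with ties away from zero (minimal bias, cheap in hardware) and
saturates at the range limits; quantization is monotone and round-trips
exactly on representable values.

Each neuron's weighted sum is computed as the hardware's combinational
adder tree would: all products accumulated exactly in a wide register, the
bias aligned and added, then **one** rounding/saturation into Q4.7. The
activation actuators square once and replace every division by a power of
two with an arithmetic right shift (floor semantics, as a hardware shifter
gives); the final conversion back to Q4.7 rounds to nearest. An exhaustive
check over all 2¹¹ input words shows both actuators within 1 ulp of the
rounded real-valued reference (the contract allows 2).

Weights are stored as 7-bit words — the width implied by a 160-synapse
memory of ~1.1 kilobits (160 × 7 = 1120 bits) — in nominal Q1.6 with a
per-layer scale restricted to powers of two, chosen as the smallest that
brings the layer's largest weight or bias into range. A power-of-two scale
keeps the datapath shift-only; it costs at most one bit of resolution
against an arbitrary real scale. Biases are quantized with the same layer
scale and included in the memory image (167 words for 30-5-2), while the
cost report keeps synapse bits and bias bits separate so either storage
convention can be read off.

Emulated fixed-point inference deviates from the float forward pass over
the *same* (dequantized) weights by at most ~0.013 in any output on random
in-range inputs — input quantization plus one MAC rounding per neuron plus
actuator error — against an asserted bound of 0.05. Comparing instead
against the pre-quantization float weights adds the 7-bit
weight-quantization error (~0.04–0.06 depending on the trained weights);
its end-to-end effect is bounded separately: quantized-datapath accuracy
on the held-out synthetic split must be within 2 percentage points of the
float accuracy (measured gap: 0).

Training is float throughout; quantization is applied once, post-training,
matching the offline-learning / on-device-inference workflow the hardware
targets.

## Data handling

Standardization is (x − µ)/σ with the **population** (divide-by-n) σ — it
is a datapath transform, not an inferential estimate; `ddof` is switchable.
Statistics are fitted on the training rows only and frozen, exactly as a
deployed device receives fixed µ, σ; zero-variance features are rejected
by name. The stratified splitter rounds per-class train counts, so class
proportions on both sides match the full data within one sample.

## Synthetic generator

The generator emulates the structure that makes the reference dataset
hard for fixed point: 569 samples, 30 features, class-1 fraction 0.37
(the malignant share of the reference data), two Gaussian classes whose
per-feature means differ by 0.8 within-class standard deviations (sign
alternating across features), and fixed per-feature scale multipliers
log-spaced over four decades (10⁻² … 10²). The separation of 0.8 puts the
Bayes accuracy near 98–99 % — comparable to what good classifiers reach on
the real data — while leaving genuine class overlap; the scale spread
makes raw features unusable (over 20 % of raw values saturate Q4.7;
after standardization essentially none do).

What it does not emulate: the real data's strong inter-feature
correlations (the 30 WBC features are mean/SE/worst triples of 10
measurements), non-Gaussian tails, and outliers. Passing tests therefore
demonstrate the pipeline's correctness and the datapath's fidelity on
separable tabular data of the right shape and scale pathology — not the
exact accuracy figure attainable on the clinical dataset. A user who loads
the actual WBC CSV through `load_csv` should expect held-out accuracy in
the mid-to-high 90s.

## Numerical choices and degenerate inputs

* Argmax ties → lowest class index; reported deterministically.
* Non-finite activations inputs, shape mismatches, >30 features, single
  class datasets, empty grids, zero-variance features → immediate
  `ValueError` naming the offence.
* Memory-image words are validated against the declared format on load;
  an out-of-range or non-hex word is rejected with its index.
* Precision/recall with a zero denominator return an explicit `UNDEFINED`
  marker, never a silent zero; macro averages propagate it.
* The macro summary row of the classification report is the unweighted
  mean of the two per-class values — the convention that reproduces the
  reference report's own arithmetic (97.5 % / 98.5 %).

## Known limitations

* Only one hidden layer and two outputs; no convolutional or multi-class
  extension.
* No modelling of RTL-level concerns: DSP48 primitives, BRAM ports,
  timing, power, clock frequency or throughput.
* The published restricted hidden-layer update is preserved only up to
  the stray A1 factor discussed above.
* Grid search re-trains from scratch per candidate; no early stopping or
  successive halving.
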