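# sqishnet

A bit-accurate software emulator and trainer for a hardware-friendly neural
classifier: a 30-5-2 multilayer perceptron that uses the piecewise-quadratic
**Sqish** activation in its hidden layer and the sigmoid-like **LogSQNL**
("square logistic sigmoid") activation at its output, trained in floating
point with classical-momentum SGD and deployed through an 11-bit **Q4.7**
fixed-point datapath whose only arithmetic is multiplies, adds and shifts.

The target use case is on-chip binary disease classification on tabular
data — the reference schema is the Wisconsin Breast Cancer layout (569
samples, 30 numeric features, benign/malignant) — where an FPGA datapath
classifies one standardized sample per clock cycle from a small programmable
weight memory. This package is for people who want to train such a
classifier, verify exactly what the fixed-point hardware would compute,
and produce the weight-memory image that programs it.

## The model

Forward pass for a standardized feature vector *x*:

    Z1 = W1ᵀx + b1,   A1 = sqish(Z1)
    Z2 = W2ᵀA1 + b2,  A2 = logsqnl(Z2),   class = argmax A2

with the shift-friendly activations

    sqish(z)   = z + z²/32            z ≥ 0
               = z + z²/2             −2 ≤ z < 0
               = 0                    z < −2

    logsqnl(z) = 1                    z > 2
               = (z − z²/4)/2 + 1/2   0 ≤ z ≤ 2
               = (z + z²/4)/2 + 1/2   −2 ≤ z < 0
               = 0                    z < −2

Training minimizes the squared error L = ½ Σ (A2 − y)² against one-hot
targets by backpropagation through the exact piecewise derivatives, with
learning rate 1/3, momentum 0.9, batch size 100 by default. Features are
standardized per feature as (x − µ)/σ with statistics fitted on the
training split only — the raw scales of WBC-like data span orders of
magnitude and would saturate the Q4.7 range immediately.

For deployment, weights are rounded to 7-bit words (nominal Q1.6 with a
per-layer power-of-two scale), exported as a plain-text memory image, and
inference is emulated word-for-word: one wide exact accumulation and a
single rounding per neuron, then the shift-based activation actuators.
The cost model counts 160 synaptic multiplications and 153 accumulation
additions per inference for the 30-5-2 topology, and 160 × 7 = 1120 bits
(~1.1 kb) of synaptic weight memory.

## Worked example

```python
import sqishnet as sq

ds = sq.generate_synthetic(seed=42)          # 569 x 30 WBC-like two-class data
model = sq.SqishNetClassifier.from_dataset(ds)
res = model.fit(epochs=200, seed=42)         # 80/20 stratified split inside
print(res.summary())
```

prints

```
Sqish/LogSQNL fixed-point MLP classifier
==============================================
topology:            30-5-2
train/test samples:  455/114
learning rate:       0.333333
momentum:            0.9
batch size:          100
epochs:              200
gradient mode:       chain_rule
final train loss:    0.008794
final train acc:     0.9912
test accuracy:       0.9561
macro precision:     0.9483
macro recall:        0.9603
synapses:            160
multiplications:     160
additions:           153
weight memory bits:  1120
```

The test accuracy is measured on the held-out split; the cost lines are
the per-inference hardware accounting for this topology. Continuing to
deployment:

```python
res.export_weight_memory("weights.mem")      # programmable memory image
rep_fx = res.evaluate(fixed_point=True)      # emulated Q4.7 inference
print(rep_fx.accuracy)                       # 0.9561 — matches float here
```

The same workflows are available from a shell via the `sqishnet` CLI
(`simulate`, `train`, `evaluate`, `quantize`, `export-mem`, `cost`), e.g.
`sqishnet cost --topology 30 5 2`.

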