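"""The 30-5-2 feed-forward classifier: parameters, forward passes, the
argmax predictor, the weight-memory image and the hardware cost model.

The network takes up to 30 standardized features, applies one hidden layer
of 5 Sqish neurons and an output layer of 2 LogSQNL neurons (one-hot
benign/malignant), and predicts the class of the most activated output.
The float forward pass is the training-time reference; the fixed-point
forward pass (:func:`forward_fixed`) replays the same dataflow through the
emulated Q4.7 datapath, one MAC rounding per neuron plus the shift-based
actuators.

Deployment artefact: a plain-text weight-memory image (one hex word per
line, layer-major, row-major, biases appended per layer) with a header
recording topology, the 7-bit nominal weight format and per-layer
power-of-two scales.  Export followed by load is bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .activations import logsqnl, sqish
from .fixed_point import (
    Q1_6,
    Q4_7,
    FixedWord,
    QFormat,
    fx_logsqnl,
    fx_mac,
    fx_sqish,
    quantize_raw,
)

__all__ = [
    "Topology",
    "NetworkParams",
    "ForwardTrace",
    "QuantizedParams",
    "CostReport",
    "WeightMemoryImage",
    "initialize_params",
    "forward",
    "forward_fixed",
    "predict",
    "count_operations",
    "quantize_params",
    "export_weight_memory",
    "load_weight_memory",
]


@dataclass(frozen=True)
class Topology:
    """Layer sizes of the network.  The hardware accepts at most 30 inputs."""

    n_inputs: int = 30
    n_hidden: int = 5
    n_outputs: int = 2

    MAX_INPUTS = 30

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValueError("all layer sizes must be positive")
        if self.n_inputs > self.MAX_INPUTS:
            raise ValueError(
                f"at most {self.MAX_INPUTS} input features supported, "
                f"got {self.n_inputs}"
            )

    @property
    def synapses(self) -> int:
        return self.n_inputs * self.n_hidden + self.n_hidden * self.n_outputs

    @property
    def biases(self) -> int:
        return self.n_hidden + self.n_outputs


@dataclass
class NetworkParams:
    """Float weights and biases.  ``W1``: (n_inputs, n_hidden); ``W2``:
    (n_hidden, n_outputs)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @property
    def topology(self) -> Topology:
        return Topology(self.W1.shape[0], self.W1.shape[1], self.W2.shape[1])

    def validate(self) -> None:
        t = self.topology
        if self.b1.shape != (t.n_hidden,) or self.W2.shape[0] != t.n_hidden:
            raise ValueError("inconsistent parameter shapes")
        if self.b2.shape != (t.n_outputs,):
            raise ValueError("inconsistent parameter shapes")
        for a in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(a)):
                raise ValueError("parameters must be finite")

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy()
        )


@dataclass
class ForwardTrace:
    """Per-layer pre-activations and activations of one forward pass (or a
    batch: arrays then have a leading sample axis)."""

    Z1: np.ndarray
    A1: np.ndarray
    Z2: np.ndarray
    A2: np.ndarray


@dataclass
class QuantizedParams:
    """Weights/biases as raw integer words in ``weight_format`` with a
    power-of-two scale per layer: real value = scale * raw * 2^-fraction."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    weight_format: QFormat = Q1_6
    scale1: float = 1.0
    scale2: float = 1.0

    @property
    def topology(self) -> Topology:
        return Topology(self.W1.shape[0], self.W1.shape[1], self.W2.shape[1])

    def effective_format(self, layer: int) -> QFormat:
        """Format whose resolution folds in the layer scale (scale = 2^k
        turns Q1.6 into Q(1+k).(6-k))."""
        scale = self.scale1 if layer == 1 else self.scale2
        k = int(round(math.log2(scale)))
        return QFormat(self.weight_format.integer_bits + k,
                       self.weight_format.fraction_bits - k)

    def dequantized(self) -> NetworkParams:
        res = self.weight_format.resolution
        return NetworkParams(
            W1=self.W1 * (self.scale1 * res),
            b1=self.b1 * (self.scale1 * res),
            W2=self.W2 * (self.scale2 * res),
            b2=self.b2 * (self.scale2 * res),
        )


@dataclass(frozen=True)
class CostReport:
    """Operation and memory accounting for one inference.

    ``accumulation_additions`` counts only the adder-tree additions inside
    the MACs ((fan_in - 1) per neuron); bias additions are excluded, which
    is the convention behind the 160-multiplications / 153-additions count
    for the 30-5-2 network.  ``weight_memory_bits`` covers synapse words
    only; ``bias_memory_bits`` is reported separately so either storage
    convention can be read off.
    """

    multiplications: int
    accumulation_additions: int
    synapses: int
    weight_memory_bits: int
    bias_memory_bits: int

    @property
    def total_memory_bits(self) -> int:
        return self.weight_memory_bits + self.bias_memory_bits


def initialize_params(topology: Topology, seed: int) -> NetworkParams:
    """Zero-mean Gaussian init scaled by 1/sqrt(fan_in); reproducible."""
    rng = np.random.default_rng(seed)
    t = topology
    return NetworkParams(
        W1=rng.normal(0.0, 1.0 / math.sqrt(t.n_inputs), (t.n_inputs, t.n_hidden)),
        b1=np.zeros(t.n_hidden),
        W2=rng.normal(0.0, 1.0 / math.sqrt(t.n_hidden), (t.n_hidden, t.n_outputs)),
        b2=np.zeros(t.n_outputs),
    )


def forward(params: NetworkParams, x: np.ndarray) -> ForwardTrace:
    """Float reference forward pass.

    ``x`` is one standardized feature vector or a (batch, n_inputs) matrix.
    Z1 = W1'x + b1, A1 = sqish(Z1), Z2 = W2'A1 + b2, A2 = logsqnl(Z2).
    """
    x = np.asarray(x, dtype=float)
    n_in = params.W1.shape[0]
    if x.shape[-1] != n_in:
        raise ValueError(f"expected {n_in} features, got {x.shape[-1]}")
    Z1 = x @ params.W1 + params.b1
    A1 = sqish(Z1)
    Z2 = A1 @ params.W2 + params.b2
    A2 = logsqnl(Z2)
    return ForwardTrace(Z1=Z1, A1=A1, Z2=Z2, A2=A2)


def forward_fixed(qparams: QuantizedParams, qx, input_format: QFormat = Q4_7) -> ForwardTrace:
    """Bit-accurate fixed-point forward pass of one sample.

    ``qx`` is a sequence of FixedWords or a vector of raw integers in
    ``input_format``.  Same dataflow as :func:`forward`, but every weighted
    sum goes through :func:`fx_mac` (one rounding per neuron) and every
    activation through the shift-based actuators.  The returned trace holds
    the dequantized real values.
    """
    t = qparams.topology
    if len(qx) != t.n_inputs:
        raise ValueError(f"expected {t.n_inputs} inputs, got {len(qx)}")
    if isinstance(qx[0], FixedWord):
        xw = list(qx)
    else:
        xw = [FixedWord(int(r), input_format) for r in qx]

    wfmt1 = qparams.effective_format(1)
    wfmt2 = qparams.effective_format(2)
    z1w, a1w = [], []
    for j in range(t.n_hidden):
        col = [FixedWord(int(r), wfmt1) for r in qparams.W1[:, j]]
        z = fx_mac(xw, col, FixedWord(int(qparams.b1[j]), wfmt1), Q4_7)
        z1w.append(z)
        a1w.append(fx_sqish(z))
    z2w, a2w = [], []
    for j in range(t.n_outputs):
        col = [FixedWord(int(r), wfmt2) for r in qparams.W2[:, j]]
        z = fx_mac(a1w, col, FixedWord(int(qparams.b2[j]), wfmt2), Q4_7)
        z2w.append(z)
        a2w.append(fx_logsqnl(z))
    return ForwardTrace(
        Z1=np.array([w.value for w in z1w]),
        A1=np.array([w.value for w in a1w]),
        Z2=np.array([w.value for w in z2w]),
        A2=np.array([w.value for w in a2w]),
    )


def predict(trace: ForwardTrace) -> int | np.ndarray:
    """Class of the most activated output neuron; ties go to the lowest
    index (np.argmax convention)."""
    A2 = np.asarray(trace.A2)
    idx = np.argmax(A2, axis=-1)
    return int(idx) if idx.ndim == 0 else idx


def count_operations(topology: Topology, weight_bits: int = 7) -> CostReport:
    """Hardware cost model for one inference on the given topology."""
    t = topology
    mults = t.n_inputs * t.n_hidden + t.n_hidden * t.n_outputs
    adds = (t.n_inputs - 1) * t.n_hidden + (t.n_hidden - 1) * t.n_outputs
    return CostReport(
        multiplications=mults,
        accumulation_additions=adds,
        synapses=t.synapses,
        weight_memory_bits=t.synapses * weight_bits,
        bias_memory_bits=t.biases * weight_bits,
    )


def _layer_scale(values: np.ndarray, fmt: QFormat) -> float:
    """Smallest power-of-two scale s with max|v|/s inside fmt's range."""
    m = float(np.max(np.abs(values))) if values.size else 0.0
    if m == 0.0:
        return 1.0
    k = max(0, math.ceil(math.log2(m / fmt.max_value)))
    return float(2 ** k)


def quantize_params(params: NetworkParams,
                    weight_format: QFormat = Q1_6) -> QuantizedParams:
    """Post-training quantization of weights and biases.

    Each layer gets the smallest power-of-two scale that brings its largest
    weight or bias magnitude into the nominal format's range, then all
    values are rounded to ``weight_format`` words of that scale.
    """
    params.validate()
    s1 = _layer_scale(np.concatenate([params.W1.ravel(), params.b1]), weight_format)
    s2 = _layer_scale(np.concatenate([params.W2.ravel(), params.b2]), weight_format)
    return QuantizedParams(
        W1=quantize_raw(params.W1 / s1, weight_format),
        b1=quantize_raw(params.b1 / s1, weight_format),
        W2=quantize_raw(params.W2 / s2, weight_format),
        b2=quantize_raw(params.b2 / s2, weight_format),
        weight_format=weight_format,
        scale1=s1,
        scale2=s2,
    )


@dataclass
class WeightMemoryImage:
    """In-memory form of the programmable weight store.

    ``words`` are raw integers, ordered layer-major and row-major within a
    layer, biases appended per layer: W1 rows, b1, W2 rows, b2.
    """

    topology: Topology
    weight_format: QFormat
    scales: tuple
    words: list = field(default_factory=list)
    version: int = 1

    def expected_words(self) -> int:
        return self.topology.synapses + self.topology.biases


def export_weight_memory(qparams: QuantizedParams) -> WeightMemoryImage:
    """Serialize quantized parameters into the memory-image word stream."""
    words = [int(w) for w in (
        *qparams.W1.ravel(), *qparams.b1, *qparams.W2.ravel(), *qparams.b2)]
    return WeightMemoryImage(
        topology=qparams.topology,
        weight_format=qparams.weight_format,
        scales=(qparams.scale1, qparams.scale2),
        words=words,
    )


def load_weight_memory(image: WeightMemoryImage) -> QuantizedParams:
    """Rebuild quantized parameters from a memory image (bit-exact inverse
    of :func:`export_weight_memory`)."""
    t = image.topology
    fmt = image.weight_format
    if len(image.words) != image.expected_words():
        raise ValueError(
            f"image has {len(image.words)} words, expected {image.expected_words()}"
        )
    for i, w in enumerate(image.words):
        if not (fmt.raw_min <= w <= fmt.raw_max):
            raise ValueError(f"word {i} value {w} outside {fmt} range")
    a = np.array(image.words, dtype=np.int64)
    n1 = t.n_inputs * t.n_hidden
    n2 = t.n_hidden * t.n_outputs
    pos = 0
    W1 = a[pos:pos + n1].reshape(t.n_inputs, t.n_hidden); pos += n1
    b1 = a[pos:pos + t.n_hidden]; pos += t.n_hidden
    W2 = a[pos:pos + n2].reshape(t.n_hidden, t.n_outputs); pos += n2
    b2 = a[pos:pos + t.n_outputs]
    return QuantizedParams(W1=W1, b1=b1, W2=W2, b2=b2, weight_format=fmt,
                           scale1=image.scales[0], scale2=image.scales[1])


def write_memory_file(image: WeightMemoryImage, path) -> None:
    """Write the plain-text image: header comments then one hex word per
    line (two's complement in the format's total bits)."""
    t = image.topology
    bits = image.weight_format.total_bits
    mask = (1 << bits) - 1
    digits = (bits + 3) // 4
    lines = [
        f"# topology {t.n_inputs} {t.n_hidden} {t.n_outputs}",
        f"# format {image.weight_format}",
        f"# version {image.version}",
        f"# scale 1 {image.scales[0]:.10g}",
        f"# scale 2 {image.scales[1]:.10g}",
    ]
    lines += [format(w & mask, f"0{digits}x") for w in image.words]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_memory_file(path) -> WeightMemoryImage:
    """Parse a plain-text memory image; malformed headers or words out of
    the declared range are rejected with their position."""
    header: dict = {"scales": {}}
    words = []
    with open(path, "r", encoding="utf-8") as fh:
        raw_lines = [ln.strip() for ln in fh if ln.strip()]
    for ln in raw_lines:
        if ln.startswith("#"):
            parts = ln[1:].split()
            if parts[0] == "topology":
                header["topology"] = Topology(*map(int, parts[1:4]))
            elif parts[0] == "format":
                header["format"] = QFormat.parse(parts[1])
            elif parts[0] == "version":
                header["version"] = int(parts[1])
            elif parts[0] == "scale":
                header["scales"][int(parts[1])] = float(parts[2])
            continue
        words.append(ln)
    for key in ("topology", "format"):
        if key not in header:
            raise ValueError(f"memory image missing '{key}' header line")
    fmt = header["format"]
    bits = fmt.total_bits
    sign = 1 << (bits - 1)
    decoded = []
    for i, tok in enumerate(words):
        try:
            u = int(tok, 16)
        except ValueError as exc:
            raise ValueError(f"word {i}: not a hex word: {tok!r}") from exc
        if u >= (1 << bits):
            raise ValueError(f"word {i} value 0x{tok} exceeds {bits}-bit {fmt}")
        decoded.append(u - (1 << bits) if u & sign else u)
    image = WeightMemoryImage(
        topology=header["topology"],
        weight_format=fmt,
        scales=(header["scales"].get(1, 1.0), header["scales"].get(2, 1.0)),
        words=decoded,
        version=header.get("version", 1),
    )
    if len(decoded) != image.expected_words():
        raise ValueError(
            f"image has {len(decoded)} words, expected {image.expected_words()}"
        )
    return image
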