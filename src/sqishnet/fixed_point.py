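"""Signed Q-format fixed-point emulation of the inference datapath.

The deployed classifier runs on an 11-bit signed fixed-point datapath in
Q4.7: four integer bits (sign included) and seven fractional bits, so the
representable range is [-8, 8 - 2^-7] in steps of 2^-7.  Standardized
inputs, pre-activations and activations all live in this format.  Weights
are stored more compactly (7-bit words by default) with a per-layer
power-of-two scale, so the whole datapath stays shift-only.

This module is a bit-accurate software model of that datapath:

* :func:`quantize` / :func:`dequantize` — round-to-nearest (ties away from
  zero) with saturation;
* :func:`fx_mac` — the multiply-accumulate of one neuron: products and sum
  are held exactly in a wide accumulator and rounded once into the output
  format, matching a combinational adder tree that completes in one cycle;
* :func:`fx_sqish` / :func:`fx_logsqnl` — the activation actuators, using
  a squaring multiply and arithmetic right shifts for the divisions by
  powers of two, exactly as the hardware MUX/adder/shifter networks do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QFormat",
    "FixedWord",
    "Q4_7",
    "Q1_6",
    "quantize",
    "dequantize",
    "fx_mac",
    "fx_sqish",
    "fx_logsqnl",
]


@dataclass(frozen=True)
class QFormat:
    """Signed two's-complement fixed-point format.

    ``integer_bits`` includes the sign bit; real value of a stored word is
    ``raw * 2**-fraction_bits``.
    """

    integer_bits: int
    fraction_bits: int

    @property
    def total_bits(self) -> int:
        return self.integer_bits + self.fraction_bits

    @property
    def raw_min(self) -> int:
        return -(1 << (self.total_bits - 1))

    @property
    def raw_max(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def resolution(self) -> float:
        return 2.0 ** -self.fraction_bits

    @property
    def min_value(self) -> float:
        return self.raw_min * self.resolution

    @property
    def max_value(self) -> float:
        return self.raw_max * self.resolution

    def __post_init__(self) -> None:
        if self.total_bits < 2:
            raise ValueError("format needs at least a sign bit and one more bit")

    def __str__(self) -> str:
        return f"Q{self.integer_bits}.{self.fraction_bits}"

    @classmethod
    def parse(cls, text: str) -> "QFormat":
        """Parse ``"Q4.7"`` / ``"4.7"`` into a QFormat."""
        body = text.strip().lstrip("Qq")
        try:
            i, f = body.split(".")
            return cls(int(i), int(f))
        except ValueError as exc:
            raise ValueError(f"cannot parse Q-format {text!r}") from exc


#: Datapath format for inputs, pre-activations and activations.
Q4_7 = QFormat(4, 7)
#: Nominal weight-storage format (7-bit words, scaled per layer).
Q1_6 = QFormat(1, 6)


@dataclass(frozen=True)
class FixedWord:
    """A raw two's-complement stored value together with its format."""

    raw: int
    fmt: QFormat

    def __post_init__(self) -> None:
        if not (self.fmt.raw_min <= self.raw <= self.fmt.raw_max):
            raise ValueError(
                f"raw word {self.raw} outside {self.fmt} range "
                f"[{self.fmt.raw_min}, {self.fmt.raw_max}]"
            )

    @property
    def value(self) -> float:
        return self.raw * self.fmt.resolution


def _round_half_away(x):
    """Round to nearest integer, ties away from zero (vectorized)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize_raw(x, fmt: QFormat):
    """Real value(s) -> saturated raw integer word(s) in ``fmt``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot quantize non-finite value")
    raw = _round_half_away(x / fmt.resolution)
    raw = np.clip(raw, fmt.raw_min, fmt.raw_max)
    return raw.astype(np.int64) if raw.ndim else int(raw)


def quantize(x: float, fmt: QFormat = Q4_7) -> FixedWord:
    """Round ``x`` to nearest representable value (ties away from zero),
    saturating at the format limits."""
    return FixedWord(quantize_raw(float(x), fmt), fmt)


def dequantize(w: FixedWord) -> float:
    """Real value of a stored word: ``raw * 2**-fraction_bits``."""
    return w.value


def _shift_round(acc: int, shift: int) -> int:
    """Scale an exact integer accumulator by 2**-shift, rounding to nearest
    with ties away from zero.  Negative shift is an exact left shift."""
    if shift <= 0:
        return acc << (-shift)
    half = 1 << (shift - 1)
    if acc >= 0:
        return (acc + half) >> shift
    return -((-acc + half) >> shift)


def _saturate(raw: int, fmt: QFormat) -> int:
    return max(fmt.raw_min, min(fmt.raw_max, raw))


def fx_mac(inputs, weights, bias: FixedWord, out_fmt: QFormat = Q4_7) -> FixedWord:
    """One neuron's multiply-accumulate on fixed-point words.

    Products and their sum are kept exactly in a wide integer accumulator
    (no intermediate rounding); the bias is aligned and added; a single
    round/saturate produces the output word.  Inputs, weights and bias may
    be in different formats.
    """
    if len(inputs) != len(weights):
        raise ValueError(
            f"length mismatch: {len(inputs)} inputs vs {len(weights)} weights"
        )
    fracs = [x.fmt.fraction_bits + w.fmt.fraction_bits for x, w in zip(inputs, weights)]
    fracs.append(bias.fmt.fraction_bits)
    wide = max(fracs) if fracs else bias.fmt.fraction_bits
    acc = 0
    for x, w in zip(inputs, weights):
        prod_frac = x.fmt.fraction_bits + w.fmt.fraction_bits
        acc += (x.raw * w.raw) << (wide - prod_frac)
    acc += bias.raw << (wide - bias.fmt.fraction_bits)
    raw = _shift_round(acc, wide - out_fmt.fraction_bits)
    return FixedWord(_saturate(raw, out_fmt), out_fmt)


def fx_sqish(w: FixedWord) -> FixedWord:
    """Shift-based Sqish actuator on a Q4.7 word.

    z^2 comes from one squaring multiply; the divisions by 32 and 2 are
    arithmetic right shifts of the double-width product; one rounding back
    to Q4.7.  Agrees with quantize(sqish(value)) within 2 ulp over the
    whole input range.
    """
    fmt = w.fmt
    f = fmt.fraction_bits
    if w.value < -2.0:
        return FixedWord(0, fmt)
    sq = w.raw * w.raw                      # scale 2^-2f, exact
    shifted = sq >> 5 if w.raw >= 0 else sq >> 1   # /32 or /2, floor shift
    acc = (w.raw << f) + shifted            # scale 2^-2f
    raw = _shift_round(acc, f)
    return FixedWord(_saturate(raw, fmt), fmt)


def fx_logsqnl(w: FixedWord) -> FixedWord:
    """Shift-based LogSQNL actuator on a Q4.7 word.

    Saturation branches by comparator; otherwise (z -/+ z^2/4)/2 + 1/2 with
    the divisions as right shifts and the offset added in the wide scale.
    Output always lands in [0, 1].
    """
    fmt = w.fmt
    f = fmt.fraction_bits
    one = 1 << f
    if w.value > 2.0:
        return FixedWord(one, fmt)
    if w.value < -2.0:
        return FixedWord(0, fmt)
    sq = w.raw * w.raw                      # scale 2^-2f
    quarter = sq >> 2
    t = (w.raw << f) - quarter if w.raw >= 0 else (w.raw << f) + quarter
    acc = (t >> 1) + (1 << (2 * f - 1))     # /2 then +1/2, scale 2^-2f
    raw = _shift_round(acc, f)
    return FixedWord(_saturate(max(0, min(one, raw)), fmt), fmt)
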