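"""Hardware-friendly piecewise-polynomial activations: Sqish and LogSQNL.

Sqish is a swish-like activation for hidden neurons,

    sqish(z) = z + z^2/32        z >= 0
             = z + z^2/2         -2 <= z < 0
             = 0                 z < -2

and LogSQNL ("square logistic sigmoid") is a sigmoid-like activation for
output neurons, saturating at 0 and 1:

    logsqnl(z) = 1                       z > 2
               = (z - z^2/4)/2 + 1/2     0 <= z <= 2
               = (z + z^2/4)/2 + 1/2     -2 <= z < 0
               = 0                       z < -2

Both are continuous, built only from additions, shifts (the divisions by
powers of two) and one squaring multiply, which is what makes them cheap in
a combinational datapath.  All functions here are exact real-valued
references; the shift-based fixed-point versions live in
:mod:`sqishnet.fixed_point`.

At an exact breakpoint the first listed branch applies (z = 0 takes the
z >= 0 branch, z = -2 the -2 <= z branch); the function values coincide by
continuity, so this only pins down which derivative value is reported at a
breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PiecewiseActivation",
    "SQISH",
    "LOGSQNL",
    "sqish",
    "sqish_derivative",
    "logsqnl",
    "logsqnl_derivative",
]


@dataclass(frozen=True)
class PiecewiseActivation:
    """Symbolic description of a branch-defined scalar activation.

    Parameters
    ----------
    name : str
        Identifier of the activation.
    breakpoints : tuple of float
        Ordered interior thresholds separating the branches.
    branches : tuple of (tuple, tuple)
        ``((lo, hi), coeffs)`` pairs; ``coeffs`` are polynomial coefficients
        in increasing degree, valid on ``lo <= z < hi`` (the last branch is
        closed above).  Intervals partition the real line.
    """

    name: str
    breakpoints: tuple
    branches: tuple

    def __post_init__(self) -> None:
        los = [b[0][0] for b in self.branches]
        his = [b[0][1] for b in self.branches]
        if los[0] != -np.inf or his[-1] != np.inf:
            raise ValueError("branches must cover the real line")
        for hi, lo_next in zip(his[:-1], los[1:]):
            if hi != lo_next:
                raise ValueError("branches must not overlap or leave gaps")

    def branch_at(self, z: float) -> tuple:
        """Polynomial coefficients of the branch containing ``z``.

        Exact breakpoints take the higher (later-starting) interval, which
        matches the case order the branches were written in.
        """
        for (lo, hi), coeffs in reversed(self.branches):
            if z >= lo:
                return coeffs
        raise AssertionError("unreachable: branches cover the real line")

    def __call__(self, z):
        z = _check_finite(z)
        out = np.zeros_like(z)
        for (lo, hi), coeffs in self.branches:
            mask = (z >= lo) & (z < hi) if hi != np.inf else (z >= lo)
            out[mask] = np.polynomial.polynomial.polyval(z[mask], coeffs)
        return out if out.ndim else float(out)


def _check_finite(z):
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("activation input must be finite")
    return z


# Branch tables; coefficients in increasing degree.  The breakpoint
# membership rule of PiecewiseActivation.__call__ (z >= lo, z < hi) encodes
# the first-listed-branch-wins convention.
SQISH = PiecewiseActivation(
    name="sqish",
    breakpoints=(-2.0, 0.0),
    branches=(
        ((-np.inf, -2.0), (0.0,)),
        ((-2.0, 0.0), (0.0, 1.0, 0.5)),
        ((0.0, np.inf), (0.0, 1.0, 1.0 / 32.0)),
    ),
)

LOGSQNL = PiecewiseActivation(
    name="logsqnl",
    breakpoints=(-2.0, 0.0, 2.0),
    branches=(
        ((-np.inf, -2.0), (0.0,)),
        ((-2.0, 0.0), (0.5, 0.5, 0.125)),
        ((0.0, 2.0), (0.5, 0.5, -0.125)),
        ((2.0, np.inf), (1.0,)),
    ),
)


def sqish(z):
    """Sqish activation, elementwise.

    Continuous, unbounded above, with global minimum -0.5 at z = -1 and a
    dead region (exact zero) below z = -2.
    """
    z = _check_finite(z)
    out = np.where(
        z >= 0,
        z + z * z / 32.0,
        np.where(z >= -2.0, z + z * z / 2.0, 0.0),
    )
    return out if out.ndim else float(out)


def sqish_derivative(z):
    """Exact derivative of :func:`sqish`.

    1 + z/16 for z >= 0, 1 + z on [-2, 0), 0 below -2.  (The printed middle
    condition of the source derivative names Z2; the argument is Z1 — the
    forced reading is used.)
    """
    z = _check_finite(z)
    out = np.where(
        z >= 0,
        1.0 + z / 16.0,
        np.where(z >= -2.0, 1.0 + z, 0.0),
    )
    return out if out.ndim else float(out)


def logsqnl(z):
    """LogSQNL activation, elementwise.  Always in [0, 1], monotone."""
    z = _check_finite(z)
    out = np.where(
        z > 2.0,
        1.0,
        np.where(
            z >= 0,
            (z - z * z / 4.0) / 2.0 + 0.5,
            np.where(z >= -2.0, (z + z * z / 4.0) / 2.0 + 0.5, 0.0),
        ),
    )
    return out if out.ndim else float(out)


def logsqnl_derivative(z):
    """Exact derivative of :func:`logsqnl`.

    (2 - z)/4 on [0, 2], (2 + z)/4 on [-2, 0), zero in both saturated
    regions.  (The condition printed as "0 <= Z2 >= 2" is read as
    0 <= Z2 <= 2, the only reading consistent with the function.)
    """
    z = _check_finite(z)
    out = np.where(
        (z >= 0) & (z <= 2.0),
        (2.0 - z) / 4.0,
        np.where((z >= -2.0) & (z < 0), (2.0 + z) / 4.0, 0.0),
    )
    return out if out.ndim else float(out)
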