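"""Convolution arithmetic: discrete convolution and layer output-size formulas.

These are the shape rules that every network plan in this package is checked
against.  A convolution with kernel ``F``, padding ``P`` and stride ``S`` maps a
spatial extent ``L`` to ``floor((L - F + 2P)/S) + 1`` (valid mode) or
``ceil(L/S)`` (same mode).  A transposed convolution inverts the mapping:
``(L - 1)·S + F - 2P`` (valid) or exactly ``L·S`` (same).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

__all__ = [
    "ConvSpec",
    "discrete_convolution_2d",
    "conv_output_size",
    "tconv_output_size",
    "leaky_relu",
]

Padding = Union[int, Literal["same"]]


@dataclass(frozen=True)
class ConvSpec:
    """Geometry of one (transposed) convolution layer.

    Parameters
    ----------
    L : input spatial size in pixels (width or height).
    F : kernel size in pixels.
    S : stride.
    P : explicit padding in pixels (valid mode) or the string ``"same"``.
    filters : output channel count; carried along for plan bookkeeping,
        irrelevant to the spatial arithmetic.
    """

    L: int
    F: int = 1
    S: int = 1
    P: Padding = 0
    filters: int = 1

    def __post_init__(self) -> None:
        if self.L < 1 or self.F < 1 or self.S < 1:
            raise ValueError("L, F and S must all be >= 1")
        if self.P != "same" and (not isinstance(self.P, int) or self.P < 0):
            raise ValueError("P must be a non-negative integer or 'same'")


def discrete_convolution_2d(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Full two-dimensional discrete convolution of image ``x`` with kernel ``h``.

    Direct evaluation of ``C[n1,n2] = sum_k1 sum_k2 h[k1,k2] x[n1-k1,n2-k2]``
    over every index where the summand is defined, i.e. the "full" convolution
    of shape ``(x.shape[0]+h.shape[0]-1, x.shape[1]+h.shape[1]-1)``.  Used as
    the brute-force oracle behind the layer-size formulas, so it is kept as a
    literal double sum rather than an FFT.
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    if x.ndim != 2 or h.ndim != 2 or x.size == 0 or h.size == 0:
        raise ValueError("x and h must be non-empty 2-D arrays")
    n1_max = x.shape[0] + h.shape[0] - 1
    n2_max = x.shape[1] + h.shape[1] - 1
    out = np.zeros((n1_max, n2_max))
    for k1 in range(h.shape[0]):
        for k2 in range(h.shape[1]):
            out[k1 : k1 + x.shape[0], k2 : k2 + x.shape[1]] += h[k1, k2] * x
    return out


def conv_output_size(spec: ConvSpec) -> int:
    """Output spatial size of a convolution layer.

    Valid mode: ``floor((L - F + 2P)/S) + 1``; same mode: ``ceil(L/S)`` (for
    input sizes divisible by the stride this is exactly ``L/S``).
    """
    if spec.P == "same":
        return math.ceil(spec.L / spec.S)
    numer = spec.L - spec.F + 2 * spec.P
    if numer < 0:
        raise ValueError(
            f"kernel {spec.F} larger than padded input {spec.L + 2 * spec.P}"
        )
    return numer // spec.S + 1


def tconv_output_size(spec: ConvSpec) -> int:
    """Output spatial size of a transposed-convolution layer.

    Valid mode: ``(L - 1)·S + F - 2P``; same mode: ``L·S`` exactly.
    """
    if spec.P == "same":
        return spec.L * spec.S
    out = (spec.L - 1) * spec.S + spec.F - 2 * spec.P
    if out < 1:
        raise ValueError(f"transposed convolution output size {out} < 1")
    return out


def leaky_relu(x, alpha: float = 0.01):
    """LeakyReLU: identity for non-negative inputs, slope ``alpha`` below zero.

    Works elementwise on scalars and arrays.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, x, alpha * x)
    return out.item() if out.ndim == 0 else out
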