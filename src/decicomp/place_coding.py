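"""Place coding of scalar attributes over magnitude-ordered input nodes.

A digit (0-9) or a digit-string length (1-4) is represented as a graded
activation pattern over a bank of nodes ordered by magnitude.  The node
tuned to the encoded value is maximally active (activation 1) and
activation falls off exponentially with the distance between a node's
preferred value and the encoded value:

    f(i, j) = exp(-sharpness * |i - (j + 1)|)       for node i = 1..n

Digit banks use 10 nodes with a steep decay (sharpness 10), so digit
codes are nearly orthogonal.  The digit-string-length bank uses 4 nodes
with a shallow decay (sharpness 1): length is a non-symbolic quantity and
its tuning curves are correspondingly broader, which gives neighbouring
length codes substantial overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningSpec",
    "PlaceCode",
    "DIGIT_TUNING",
    "LENGTH_TUNING",
    "encode_value",
]


@dataclass(frozen=True)
class TuningSpec:
    """Geometry of one input bank.

    Parameters
    ----------
    n_nodes : int
        Number of magnitude-ordered nodes in the bank.
    sharpness : float
        Non-negative exponential decay rate of the tuning curve.
    label : str
        Attribute name used in error messages ("digit", "length", ...).
    value_range : tuple of int
        Inclusive (low, high) range of encodable values.
    """

    n_nodes: int
    sharpness: float
    label: str = "value"
    value_range: tuple[int, int] = (0, 9)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be a positive integer")
        if self.sharpness < 0:
            raise ValueError("sharpness must be non-negative")


#: Tuning of the single-digit banks: 10 nodes, steep decay.
DIGIT_TUNING = TuningSpec(n_nodes=10, sharpness=10.0, label="digit", value_range=(0, 9))

#: Tuning of the number-of-digits bank: 4 nodes, broad decay, values 1-4.
LENGTH_TUNING = TuningSpec(n_nodes=4, sharpness=1.0, label="number of digits", value_range=(1, 4))


@dataclass(frozen=True)
class PlaceCode:
    """Activation pattern of one bank together with the value it encodes."""

    activations: np.ndarray
    encoded_value: int

    def __len__(self) -> int:
        return len(self.activations)


def encode_value(j: int, spec: TuningSpec) -> PlaceCode:
    """Encode the attribute value ``j`` on the bank described by ``spec``.

    Node ``i`` (1-based) receives activation ``exp(-sharpness * |i - (j+1)|)``,
    so the node at position ``j + 1`` peaks at exactly 1.

    Raises
    ------
    ValueError
        If ``j`` lies outside the bank's encodable range.
    """
    j = int(j)
    lo, hi = spec.value_range
    if not (lo <= j <= hi) or j - lo + 1 > spec.n_nodes:
        raise ValueError(
            f"{spec.label} value {j} outside the encodable range [{lo}, {hi}] "
            f"of a {spec.n_nodes}-node bank"
        )
    # peak at node j + 1 for 0-based digit values; banks whose lowest value
    # is not 0 (the length bank, values 1-4 on 4 nodes) shift accordingly
    peak = j - lo + 1
    nodes = np.arange(1, spec.n_nodes + 1)
    acts = np.exp(-spec.sharpness * np.abs(nodes - peak))
    return PlaceCode(activations=acts, encoded_value=j)


def code_overlap(a: PlaceCode, b: PlaceCode) -> float:
    """Dot-product overlap between two codes from the same bank."""
    if len(a) != len(b):
        raise ValueError("codes come from banks of different sizes")
    return float(a.activations @ b.activations)
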