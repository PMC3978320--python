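"""Trainable two-choice comparison networks.

One comparator decides which of two place-coded values is larger.  Its
input layer is the concatenation of two banks (left value, right value),
fully connected to two comparison nodes coding "left larger" (L) and
"right larger" (R).  The comparison nodes inhibit each other with a fixed
weight of -2 and pass their net input through a logistic sigmoid.

The same architecture is instantiated four times in the full model:
units, tenths and hundredths (10-node digit banks, shared trained
weights) and number-of-digits (4-node banks).  Networks are trained with
the delta rule on randomly sampled ordered pairs of unequal values; the
digit sampler over-represents 0 (weight 1.15) and 1 (weight 1.05), which
strengthens the weights serving comparisons against zero and is the
mechanism behind the faster processing of decimals with a zero tenth
digit.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as sigmoid

from .place_coding import DIGIT_TUNING, LENGTH_TUNING, PlaceCode, TuningSpec, encode_value

__all__ = [
    "ComparatorWeights",
    "TrainingConfig",
    "DIGIT_FREQUENCY_WEIGHTS",
    "digit_training_config",
    "length_training_config",
    "sample_value",
    "sample_training_pair",
    "train_delta",
    "comparator_forward",
    "feedforward_input",
    "evidence",
    "decision_accuracy",
    "save_weights",
    "load_weights",
]

#: Lateral inhibition between the two comparison nodes; never trained.
W_INH_COMP = -2.0

#: Relative sampling weights of digits 0-9 during training: 0 occurs 15%
#: and 1 occurs 5% more often than the remaining digits.
DIGIT_FREQUENCY_WEIGHTS = np.array([1.15, 1.05, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])


@dataclass(frozen=True)
class TrainingConfig:
    """Schedule of one comparator's delta-rule training."""

    n_trials: int
    learning_rate: float = 0.01
    init_range: tuple[float, float] = (-1.0, 1.0)
    frequency_weights: np.ndarray = field(default_factory=lambda: DIGIT_FREQUENCY_WEIGHTS.copy())

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        w = np.asarray(self.frequency_weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("frequency_weights must all be positive")
        object.__setattr__(self, "frequency_weights", w)


def digit_training_config(n_trials: int = 120_000, **kw) -> TrainingConfig:
    """Default digit-network schedule: 120,000 zero-biased trials."""
    return TrainingConfig(n_trials=n_trials, frequency_weights=DIGIT_FREQUENCY_WEIGHTS.copy(), **kw)


def length_training_config(n_trials: int = 100_000, **kw) -> TrainingConfig:
    """Default length-network schedule: 100,000 uniform trials over lengths 1-4.

    Spread over only 12 ordered unequal pairs this trains each length
    comparison far more often than each of the 90 digit comparisons,
    which makes the number-of-digits comparison the faster one.
    """
    return TrainingConfig(n_trials=n_trials, frequency_weights=np.ones(4), **kw)


@dataclass
class ComparatorWeights:
    """Trained feedforward weights of one comparison network.

    ``W`` maps the concatenated input banks (left then right, 2 * n_nodes
    inputs) onto the two comparison nodes, row 0 = L ("left larger"),
    row 1 = R ("right larger").  ``accuracy`` is the fraction of ordered
    unequal value pairs the network decides correctly.
    """

    W: np.ndarray
    spec: TuningSpec
    w_inh_comp: float = W_INH_COMP
    accuracy: float = float("nan")

    @property
    def n_nodes(self) -> int:
        return self.spec.n_nodes


def _values(spec: TuningSpec) -> np.ndarray:
    lo, hi = spec.value_range
    return np.arange(lo, hi + 1)


def _pair_inputs(spec: TuningSpec) -> dict[tuple[int, int], np.ndarray]:
    codes = {v: encode_value(v, spec).activations for v in _values(spec)}
    return {
        (a, b): np.concatenate([codes[a], codes[b]])
        for a in _values(spec)
        for b in _values(spec)
    }


def sample_value(frequency_weights: np.ndarray, values: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one value with probability proportional to its frequency weight."""
    p = frequency_weights / frequency_weights.sum()
    return int(rng.choice(values, p=p))


def sample_training_pair(
    config: TrainingConfig, spec: TuningSpec, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw an ordered pair of unequal values; equal draws are rejected."""
    values = _values(spec)
    p = config.frequency_weights / config.frequency_weights.sum()
    while True:
        a, b = rng.choice(values, size=2, p=p)
        if a != b:
            return int(a), int(b)


def feedforward_input(weights: ComparatorWeights, left: PlaceCode, right: PlaceCode) -> np.ndarray:
    """Raw weighted-sum net input of the two comparison nodes, (net_L, net_R)."""
    if len(left) != weights.n_nodes or len(right) != weights.n_nodes:
        raise ValueError(
            f"input bank size ({len(left)}, {len(right)}) does not match the "
            f"network's {weights.n_nodes}-node banks"
        )
    x = np.concatenate([left.activations, right.activations])
    return weights.W @ x


def evidence(weights: ComparatorWeights, left: PlaceCode, right: PlaceCode) -> np.ndarray:
    """Single-pass comparison-node activations sigmoid(W x), in (0, 1)."""
    return sigmoid(feedforward_input(weights, left, right))


def comparator_forward(
    left: PlaceCode,
    right: PlaceCode,
    weights: ComparatorWeights,
    iterate: bool = True,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Activations (a_L, a_R) of the comparison nodes for one input pair.

    With ``iterate=True`` the mutual inhibition ``w_inh_comp`` is applied
    and the pair is relaxed to its fixed point
    ``a_s = sigmoid(net_s + w_inh_comp * a_other)``; otherwise a single
    feedforward pass with the opposing activation at 0 is returned (the
    convention used during training).
    """
    net = feedforward_input(weights, left, right)
    a = sigmoid(net)
    if not iterate:
        return float(a[0]), float(a[1])
    for _ in range(max_iter):
        new = sigmoid(net + weights.w_inh_comp * a[::-1])
        if np.max(np.abs(new - a)) < tol:
            a = new
            break
        a = new
    return float(a[0]), float(a[1])


def decision_accuracy(weights: ComparatorWeights) -> float:
    """Fraction of all ordered unequal value pairs decided correctly."""
    inputs = _pair_inputs(weights.spec)
    n_ok = 0
    n_all = 0
    for (a, b), x in inputs.items():
        if a == b:
            continue
        net = weights.W @ x
        n_all += 1
        n_ok += (net[0] > net[1]) == (a > b)
    return n_ok / n_all


def train_delta(
    config: TrainingConfig,
    spec: TuningSpec,
    rng: np.random.Generator,
) -> ComparatorWeights:
    """Train one comparator with the online delta rule.

    Each trial presents one ordered unequal pair; the comparison nodes
    are evaluated in a single feedforward pass (the opposing node's
    contribution at 0) and the weights move toward the target (1, 0)
    when the left value is larger, (0, 1) otherwise:

        W <- W + learning_rate * (target - a) x^T

    Returns the trained weights with their exhaustive decision accuracy
    filled in; a network that has not reached 100% simply carries the
    achieved accuracy (callers that require a converged comparator check
    this field).
    """
    values = _values(spec)
    if config.frequency_weights.shape != values.shape:
        raise ValueError(
            f"frequency_weights has length {len(config.frequency_weights)}, "
            f"expected one weight per value ({len(values)})"
        )
    lo, hi = config.init_range
    W = rng.uniform(lo, hi, size=(2, 2 * spec.n_nodes))
    weights = ComparatorWeights(W=W, spec=spec)

    if config.n_trials > 0:
        pair_x = _pair_inputs(spec)
        pairs = [(a, b) for a in values for b in values if a != b]
        X = np.stack([pair_x[p] for p in pairs])
        T = np.array([[1.0, 0.0] if a > b else [0.0, 1.0] for a, b in pairs])
        # trial sequence: independent weighted draws per side, equal pairs redrawn
        p = config.frequency_weights / config.frequency_weights.sum()
        pair_p = np.array([p[a - values[0]] * p[b - values[0]] for a, b in pairs])
        pair_p /= pair_p.sum()
        seq = rng.choice(len(pairs), size=config.n_trials, p=pair_p)
        lr = config.learning_rate
        for k in seq:
            x = X[k]
            a = sigmoid(W @ x)
            W += lr * np.outer(T[k] - a, x)

    weights.accuracy = decision_accuracy(weights)
    return weights


# ---------------------------------------------------------------------------
# plain-text serialization


def save_weights(weights: ComparatorWeights, config: TrainingConfig | None, path) -> None:
    """Write trained weights as CSV with a JSON metadata header line."""
    meta = {
        "n_nodes": weights.spec.n_nodes,
        "sharpness": weights.spec.sharpness,
        "label": weights.spec.label,
        "value_range": list(weights.spec.value_range),
        "w_inh_comp": weights.w_inh_comp,
        "accuracy": weights.accuracy,
    }
    if config is not None:
        meta["training"] = {
            "n_trials": config.n_trials,
            "learning_rate": config.learning_rate,
            "init_range": list(config.init_range),
            "frequency_weights": config.frequency_weights.tolist(),
        }
    buf = io.StringIO()
    np.savetxt(buf, weights.W, delimiter=",")
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write(buf.getvalue())


def load_weights(path) -> ComparatorWeights:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ValueError(f"{path}: missing metadata header")
        meta = json.loads(header[2:])
        W = np.loadtxt(fh, delimiter=",")
    spec = TuningSpec(
        n_nodes=meta["n_nodes"],
        sharpness=meta["sharpness"],
        label=meta["label"],
        value_range=tuple(meta["value_range"]),
    )
    return ComparatorWeights(
        W=W, spec=spec, w_inh_comp=meta["w_inh_comp"], accuracy=meta["accuracy"]
    )
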